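"""Overlapping 3-mer decomposition and typographical-error classification.

A token of length L decomposes into L-2 overlapping 3-mers. A *transition*
pairs the canonical token's 3-mer at index i with the typo token's 3-mer at
the same index; transitions beyond the typo's last 3-mer are ABSENT (target
None). Each non-identity transition falls into exactly one of six error
categories.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from tblat.errors import UnalignableTokenError

__all__ = [
    "K",
    "ErrorCategory",
    "ErrorTypeProfile",
    "KmerSequence",
    "PairAlignment",
    "TokenPairCorpus",
    "TransitionRecord",
    "classify_transition",
    "kmers",
    "pair_transitions",
    "profile_errors",
]

K = 3  # all shipped statistics assume 3-mers; kept as a constant for clarity


class ErrorCategory(enum.Enum):
    IDENTITY = "identity"
    SHIFT = "shift"
    SINGLE_REPLACEMENT = "single_replacement"
    DOUBLE_REPLACEMENT = "double_replacement"
    GAP_SHIFT = "gap_shift"
    INVERSION = "inversion"
    OTHER = "other"


#: The six non-identity categories, in classification precedence order.
NON_IDENTITY_CATEGORIES = (
    ErrorCategory.INVERSION,
    ErrorCategory.GAP_SHIFT,
    ErrorCategory.SHIFT,
    ErrorCategory.SINGLE_REPLACEMENT,
    ErrorCategory.DOUBLE_REPLACEMENT,
    ErrorCategory.OTHER,
)


@dataclass(frozen=True)
class KmerSequence:
    token: str
    k: int
    kmers: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kmers)

    def __iter__(self) -> Iterator[str]:
        return iter(self.kmers)

    def __getitem__(self, i: int) -> str:
        return self.kmers[i]


@dataclass(frozen=True)
class TransitionRecord:
    """Index-aligned pairing of a canonical 3-mer with a typo 3-mer.

    ``target`` is None (ABSENT) when the typo token has fewer 3-mers than the
    canonical token.
    """

    position: int
    source: str
    target: str | None

    @property
    def absent(self) -> bool:
        return self.target is None


@dataclass(frozen=True)
class PairAlignment:
    """All transition records for a (canonical, typo) pair.

    ``unmatched_targets`` holds surplus typo 3-mers when the typo token is
    longer than the canonical one; they generate no TransitionRecord.
    """

    records: tuple[TransitionRecord, ...]
    unmatched_targets: tuple[str, ...]

    def __iter__(self) -> Iterator[TransitionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def kmers(token: str, k: int = K) -> KmerSequence:
    """All orderly overlapping length-``k`` substrings of ``token``.

    >>> kmers("abnormal").kmers
    ('abn', 'bno', 'nor', 'orm', 'rma', 'mal')
    """
    if len(token) < k:
        raise UnalignableTokenError(
            f"token {token!r} is shorter than k={k} and cannot be aligned"
        )
    return KmerSequence(token, k, tuple(token[i : i + k] for i in range(len(token) - k + 1)))


def pair_transitions(canonical: str, typo: str) -> PairAlignment:
    """Index-aligned 3-mer transitions from ``canonical`` to ``typo``.

    One record per canonical 3-mer index; indices beyond the typo's last
    3-mer carry an ABSENT target. Surplus typo 3-mers (typo longer than
    canonical) are reported separately.
    """
    src = kmers(canonical).kmers
    tgt = kmers(typo).kmers
    records = tuple(
        TransitionRecord(i, s, tgt[i] if i < len(tgt) else None)
        for i, s in enumerate(src)
    )
    return PairAlignment(records, tuple(tgt[len(src):]))


def classify_transition(source: str, target: str) -> ErrorCategory:
    """Assign exactly one error category to a 3-mer transition.

    Predicates are evaluated most-specific first: IDENTITY, INVERSION,
    GAP_SHIFT, SHIFT, SINGLE_REPLACEMENT, DOUBLE_REPLACEMENT, OTHER, so the
    rarer structured categories are not swallowed by the broad Hamming
    classes (an adjacent swap also has Hamming distance 2, for example).
    """
    if len(source) != K or len(target) != K:
        raise ValueError(f"classify_transition requires length-{K} strings")
    if source == target:
        return ErrorCategory.IDENTITY
    if _is_inversion(source, target):
        return ErrorCategory.INVERSION
    if _is_gap_shift(source, target):
        return ErrorCategory.GAP_SHIFT
    if _is_shift(source, target):
        return ErrorCategory.SHIFT
    ham = sum(a != b for a, b in zip(source, target))
    if ham == 1:
        return ErrorCategory.SINGLE_REPLACEMENT
    if ham == 2:
        return ErrorCategory.DOUBLE_REPLACEMENT
    return ErrorCategory.OTHER


def _is_inversion(s: str, t: str) -> bool:
    # target equals source with two characters swapped: tar -> atr, tra, rat
    for i, j in ((0, 1), (1, 2), (0, 2)):
        chars = list(s)
        chars[i], chars[j] = chars[j], chars[i]
        if "".join(chars) == t:
            return True
    return False


def _is_gap_shift(s: str, t: str) -> bool:
    # character inserted in the middle: target matches s[i], wildcard, s[i+1]
    return any(t[0] == s[i] and t[2] == s[i + 1] for i in (0, 1))


def _is_shift(s: str, t: str) -> bool:
    # two of the three characters shifted one position left or right:
    # met -> ame (right: t[1:] == s[:2]) or met -> eta (left: t[:2] == s[1:])
    return t[1:] == s[:2] or t[:2] == s[1:]


class TokenPairCorpus:
    """A corpus of (canonical, typo) token pairs, the matrix training substrate."""

    def __init__(self, pairs: Iterable[tuple[str, str]], metadata: Mapping | None = None):
        self.pairs: list[tuple[str, str]] = [(c.lower(), t.lower()) for c, t in pairs]
        self.metadata: dict = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    @classmethod
    def from_file(cls, path: str | Path) -> "TokenPairCorpus":
        """Read a two-column TSV ``canonical<TAB>typo``.

        A consolidated-row variant ``canonical<TAB>typo1,typo2,...`` is also
        accepted; blank lines and ``#`` comments are skipped.
        """
        pairs: list[tuple[str, str]] = []
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"expected 2 tab-separated columns, got {len(cols)}: {raw!r}")
            canonical = cols[0].strip()
            for typo in cols[1].split(","):
                typo = typo.strip()
                if typo:
                    pairs.append((canonical, typo))
        return cls(pairs, {"source": str(path)})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for canonical, typo in self.pairs:
                fh.write(f"{canonical}\t{typo}\n")


@dataclass(frozen=True)
class ErrorTypeProfile:
    """Relative frequencies of the six non-identity error categories.

    Frequencies are computed over aligned non-identity transitions and sum
    to 1; they double as penalty weights in the aligner.
    """

    frequencies: Mapping[ErrorCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        if any(v < 0 for v in freqs.values()):
            raise ValueError("category frequencies must be non-negative")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category frequencies must sum to 1, got {total}")
        object.__setattr__(self, "frequencies", freqs)

    def frequency(self, category: ErrorCategory) -> float:
        return self.frequencies.get(category, 0.0)

    @classmethod
    def default(cls) -> "ErrorTypeProfile":
        """Category mix observed on a large clinical typo corpus."""
        return cls(
            {
                ErrorCategory.SHIFT: 0.4225,
                ErrorCategory.SINGLE_REPLACEMENT: 0.1890,
                ErrorCategory.DOUBLE_REPLACEMENT: 0.0879,
                ErrorCategory.GAP_SHIFT: 0.0563,
                ErrorCategory.INVERSION: 0.0302,
                ErrorCategory.OTHER: 0.2141,
            }
        )


def profile_errors(pairs: TokenPairCorpus | Sequence[tuple[str, str]]) -> ErrorTypeProfile:
    """Relative category frequencies over all aligned non-identity transitions.

    Identity pairs and ABSENT records contribute nothing. Raises ValueError
    when the corpus holds no non-identity transitions.
    """
    counts: dict[ErrorCategory, int] = {c: 0 for c in NON_IDENTITY_CATEGORIES}
    total = 0
    for canonical, typo in pairs:
        if canonical == typo:
            continue
        for rec in pair_transitions(canonical, typo):
            if rec.target is None:
                continue
            cat = classify_transition(rec.source, rec.target)
            if cat is ErrorCategory.IDENTITY:
                continue
            counts[cat] += 1
            total += 1
    if total == 0:
        raise ValueError("corpus contains no non-identity transitions")
    return ErrorTypeProfile({c: n / total for c, n in counts.items()})
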