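"""Build, prune, serialize and load the 3-mer transition scoring matrix.

For each source 3-mer s observed in canonical tokens, P(s -> t) is the
relative frequency of the index-aligned transition s -> t over all
(canonical, typo) pairs with canonical != typo. Normalization is per source
over all observed targets *before* pruning; entries below the prune
threshold are then dropped (row sums after pruning are therefore <= 1).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from tblat.errors import EmptyMatrixError, MatrixFormatError
from tblat.kmers import TokenPairCorpus, pair_transitions

__all__ = ["TransitionMatrix", "build_matrix", "save_matrix", "load_matrix"]

DEFAULT_PRUNE = 0.01
_DECIMALS = 6  # serialized probability precision


@dataclass
class TransitionMatrix:
    """source 3-mer -> {target 3-mer -> probability in (0, 1]}."""

    entries: dict[str, dict[str, float]] = field(default_factory=dict)
    prune_threshold: float = DEFAULT_PRUNE
    provenance: str = ""

    def get(self, source: str, target: str) -> float | None:
        row = self.entries.get(source)
        if row is None:
            return None
        return row.get(target)

    def row(self, source: str) -> Mapping[str, float]:
        return self.entries.get(source, {})

    def identity(self, source: str) -> float | None:
        """The identity transition value m[s][s], if stored."""
        return self.get(source, source)

    def mean_identity(self) -> float:
        """Mean of stored identity values; 0 for a matrix with none."""
        vals = [row[s] for s, row in self.entries.items() if s in row]
        return sum(vals) / len(vals) if vals else 0.0

    def __contains__(self, source: str) -> bool:
        return source in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.prune_threshold == other.prune_threshold
        )


def build_matrix(
    corpus: TokenPairCorpus | Iterable[tuple[str, str]],
    prune_threshold: float = DEFAULT_PRUNE,
    provenance: str = "",
) -> TransitionMatrix:
    """Aggregate index-aligned transition frequencies into a scoring matrix.

    Identity pairs (canonical == typo) are excluded entirely; ABSENT records
    contribute to no entry. Each listed pair contributes each of its aligned
    transitions once (duplicate pairs count multiply). Raises
    EmptyMatrixError when no usable transitions exist.
    """
    if not 0 <= prune_threshold < 1:
        raise ValueError("prune_threshold must be in [0, 1)")
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for canonical, typo in corpus:
        if canonical == typo:
            continue
        for rec in pair_transitions(canonical, typo):
            if rec.target is not None:
                counts[rec.source][rec.target] += 1
    if not counts:
        raise EmptyMatrixError(
            "corpus contains no non-identity pairs; matrix would be empty"
        )
    entries: dict[str, dict[str, float]] = {}
    for source, targets in counts.items():
        denom = sum(targets.values())
        row = {
            t: round(n / denom, _DECIMALS)
            for t, n in targets.items()
            if n / denom >= prune_threshold
        }
        if row:
            entries[source] = row
    return TransitionMatrix(entries, prune_threshold, provenance)


def save_matrix(m: TransitionMatrix, path: str | Path) -> None:
    """Write a three-column TSV ``source<TAB>target<TAB>probability``.

    Probabilities carry 6 decimal places; a commented header records the
    prune threshold and provenance.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# prune_threshold={m.prune_threshold}\n")
        fh.write(f"# provenance={m.provenance}\n")
        for source in sorted(m.entries):
            row = m.entries[source]
            for target in sorted(row, key=lambda t: (-row[t], t)):
                fh.write(f"{source}\t{target}\t{row[target]:.{_DECIMALS}f}\n")


def load_matrix(path: str | Path) -> TransitionMatrix:
    """Read a matrix TSV written by :func:`save_matrix`.

    Raises MatrixFormatError (with line number) on malformed rows or
    probabilities outside (0, 1].
    """
    entries: dict[str, dict[str, float]] = {}
    prune_threshold = DEFAULT_PRUNE
    provenance = ""
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("prune_threshold="):
                try:
                    prune_threshold = float(body.split("=", 1)[1])
                except ValueError:
                    raise MatrixFormatError("unparseable prune_threshold", lineno)
            elif body.startswith("provenance="):
                provenance = body.split("=", 1)[1]
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise MatrixFormatError(
                f"expected 3 tab-separated columns, got {len(cols)}", lineno
            )
        source, target, prob_s = cols
        try:
            prob = float(prob_s)
        except ValueError:
            raise MatrixFormatError(f"unparseable probability {prob_s!r}", lineno)
        if not 0 < prob <= 1:
            raise MatrixFormatError(f"probability {prob} outside (0, 1]", lineno)
        entries.setdefault(source, {})[target] = prob
    if not entries:
        raise MatrixFormatError(f"no matrix entries found in {path}")
    return TransitionMatrix(entries, prune_threshold, provenance)


def matrix_to_json(m: TransitionMatrix) -> str:
    """Single-document JSON export, convenient for embedding."""
    return json.dumps(
        {
            "prune_threshold": m.prune_threshold,
            "provenance": m.provenance,
            "entries": m.entries,
        },
        indent=1,
        sort_keys=True,
    )


def matrix_from_json(text: str) -> TransitionMatrix:
    doc = json.loads(text)
    entries = {s: dict(row) for s, row in doc["entries"].items()}
    for s, row in entries.items():
        for t, p in row.items():
            if not 0 < p <= 1:
                raise MatrixFormatError(f"probability {p} for {s}->{t} outside (0, 1]")
    return TransitionMatrix(entries, doc.get("prune_threshold", DEFAULT_PRUNE), doc.get("provenance", ""))
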