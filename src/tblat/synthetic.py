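"""Synthetic data: typo generation, pair corpora with known transition
statistics, and annotated-document perturbation.

Every generator is seed-deterministic, so tests and benchmarks can use the
generating parameters as oracles. The number of errors introduced into a
token is banded by its length: 1 error below 10 characters, 3 for 10-17,
4 from 18 upwards.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from tblat.kmers import (
    ErrorCategory,
    TokenPairCorpus,
    classify_transition,
    pair_transitions,
)

__all__ = [
    "TypoSpec",
    "band_error_count",
    "make_typo",
    "gen_typo_errors",
    "gen_pair_corpus",
    "perturb_corpus",
    "AnnotatedDoc",
]

_ALPHABET = string.ascii_lowercase

GENERATABLE_CATEGORIES = (
    ErrorCategory.SHIFT,
    ErrorCategory.SINGLE_REPLACEMENT,
    ErrorCategory.DOUBLE_REPLACEMENT,
    ErrorCategory.GAP_SHIFT,
    ErrorCategory.INVERSION,
)

_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class TypoSpec:
    """Weighted category mix and seed for typo generation.

    The default mix is uniform over shift, single replacement and inversion —
    the three categories used for systematic label perturbation.
    """

    categories: Mapping[ErrorCategory, float] = field(
        default_factory=lambda: {
            ErrorCategory.SHIFT: 1 / 3,
            ErrorCategory.SINGLE_REPLACEMENT: 1 / 3,
            ErrorCategory.INVERSION: 1 / 3,
        }
    )
    seed: int = 42

    def __post_init__(self) -> None:
        cats = dict(self.categories)
        if not cats:
            raise ValueError("at least one category required")
        if any(w < 0 for w in cats.values()):
            raise ValueError("weights must be non-negative")
        total = sum(cats.values())
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        object.__setattr__(
            self, "categories", {c: w / total for c, w in cats.items()}
        )
        for cat in cats:
            if cat not in GENERATABLE_CATEGORIES:
                raise ValueError(f"cannot generate category {cat}")


def band_error_count(length: int) -> int:
    """Errors to introduce for a token length: 1 / 3 / 4 for <10 / 10-17 / >=18."""
    if length < 10:
        return 1
    if length <= 17:
        return 3
    return 4


def _random_char(rng: np.random.Generator, exclude: str = "") -> str:
    choices = [c for c in _ALPHABET if c not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def _apply_edit(
    token: str, category: ErrorCategory, pos: int, rng: np.random.Generator
) -> str:
    """One raw edit of the given category at character position ``pos``."""
    if category is ErrorCategory.SHIFT:
        # insertion (duplicate or random char) or deletion shifts the tail
        mode = int(rng.integers(0, 3))
        if mode == 0:
            return token[:pos] + token[pos] + token[pos:]  # duplicate char
        if mode == 1:
            return token[:pos] + _random_char(rng) + token[pos:]
        return token[:pos] + token[pos + 1 :]  # deletion
    if category is ErrorCategory.SINGLE_REPLACEMENT:
        return token[:pos] + _random_char(rng, token[pos]) + token[pos + 1 :]
    if category is ErrorCategory.DOUBLE_REPLACEMENT:
        if pos + 1 >= len(token):
            pos -= 1
        return (
            token[:pos]
            + _random_char(rng, token[pos])
            + _random_char(rng, token[pos + 1])
            + token[pos + 2 :]
        )
    if category is ErrorCategory.GAP_SHIFT:
        return token[:pos] + _random_char(rng) + token[pos:]
    if category is ErrorCategory.INVERSION:
        if pos + 1 >= len(token):
            pos -= 1
        if token[pos] == token[pos + 1]:
            raise _RetryEdit
        return token[:pos] + token[pos + 1] + token[pos] + token[pos + 2 :]
    raise ValueError(f"cannot generate category {category}")


class _RetryEdit(Exception):
    pass


def _has_category(canonical: str, typo: str, category: ErrorCategory) -> bool:
    if len(typo) < 3:
        return False
    return any(
        classify_transition(rec.source, rec.target) is category
        for rec in pair_transitions(canonical, typo)
        if rec.target is not None
    )


def make_typo(
    token: str, category: ErrorCategory, rng: np.random.Generator
) -> str:
    """One typo of ``token`` whose aligned transitions include ``category``.

    Retries random draws until the classify-based check passes; the same rng
    state always yields the same output.
    """
    if len(token) < 4:
        raise ValueError(f"token {token!r} too short to host a typo (need >= 4 chars)")
    if category not in GENERATABLE_CATEGORIES:
        raise ValueError(f"cannot generate category {category}")
    for _ in range(_MAX_ATTEMPTS):
        pos = int(rng.integers(1, len(token) - 1))  # internal positions only
        try:
            typo = _apply_edit(token, category, pos, rng)
        except _RetryEdit:
            continue
        if typo != token and _has_category(token, typo, category):
            return typo
    raise ValueError(f"could not host a {category.value} edit in {token!r}")


def _typo_with_edits(
    token: str, spec: TypoSpec, n_errors: int, rng: np.random.Generator
) -> tuple[str, list[ErrorCategory]]:
    """Apply ``n_errors`` sequential edits at distinct, non-adjacent positions."""
    cats = list(spec.categories)
    weights = np.array([spec.categories[c] for c in cats])
    for _ in range(_MAX_ATTEMPTS):
        result = token
        used: set[int] = set()
        edits: list[ErrorCategory] = []
        ok = True
        for _ in range(n_errors):
            cat = cats[int(rng.choice(len(cats), p=weights))]
            free = [
                p
                for p in range(1, len(result) - 1)
                if all(abs(p - u) > 1 for u in used)
            ]
            if not free:
                ok = False
                break
            pos = free[int(rng.integers(0, len(free)))]
            try:
                edited = _apply_edit(result, cat, pos, rng)
            except _RetryEdit:
                ok = False
                break
            if edited == result:
                ok = False
                break
            used.add(pos)
            result = edited
            edits.append(cat)
        if ok and result != token:
            return result, edits
    raise ValueError(f"could not place {n_errors} non-adjacent edits in {token!r}")


def gen_typo_errors(
    token: str,
    spec: TypoSpec,
    n_variants: int = 5,
    return_edits: bool = False,
):
    """Length-banded typo variants of ``token``.

    Each variant carries exactly ``band_error_count(len(token))`` error
    events, applied sequentially at distinct non-adjacent positions. With
    ``return_edits`` the per-variant category logs are returned too.
    """
    if len(token) < 4:
        raise ValueError(f"token {token!r} too short (need >= 4 chars)")
    rng = np.random.default_rng(spec.seed)
    n_errors = band_error_count(len(token))
    variants: dict[str, list[ErrorCategory]] = {}
    attempts = 0
    while len(variants) < n_variants and attempts < _MAX_ATTEMPTS * n_variants:
        attempts += 1
        typo, edits = _typo_with_edits(token, spec, n_errors, rng)
        if typo not in variants:
            variants[typo] = edits
    if return_edits:
        return dict(variants)
    return set(variants)


def gen_pair_corpus(
    vocab: Iterable[str],
    transition_probs: Mapping[str, Mapping[str, float]],
    n: int,
    seed: int,
) -> TokenPairCorpus:
    """A pair corpus whose aligned 3-mer transitions are i.i.d. draws.

    Vocabulary entries must be single 3-mers (length 3) so that the sampled
    target *is* the typo token and the transitions are exactly the draws —
    the generating ``transition_probs`` then serve as the recovery oracle.
    Identity draws produce identity pairs, which the matrix builder ignores;
    a distribution that can only produce identity pairs is rejected.
    """
    vocab = sorted(set(vocab))
    if not vocab:
        raise ValueError("vocab must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    for tok in vocab:
        if len(tok) != 3:
            raise ValueError(
                f"gen_pair_corpus requires length-3 vocabulary entries, got {tok!r}"
            )
        if tok not in transition_probs:
            raise ValueError(f"no transition row for {tok!r}")
        row = transition_probs[tok]
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"row for {tok!r} sums to {total}, expected 1")
    if all(
        set(transition_probs[tok]) == {tok} for tok in vocab
    ):
        raise ValueError(
            "distribution only produces identity pairs; no typo corpus possible"
        )
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for _ in range(n):
        src = vocab[int(rng.integers(0, len(vocab)))]
        row = transition_probs[src]
        targets = sorted(row)
        probs = np.array([row[t] for t in targets])
        tgt = targets[int(rng.choice(len(targets), p=probs / probs.sum()))]
        pairs.append((src, tgt))
    return TokenPairCorpus(
        pairs,
        metadata={
            "generator": "gen_pair_corpus",
            "seed": seed,
            "n": n,
            "transition_probs": {s: dict(r) for s, r in transition_probs.items()},
        },
    )


@dataclass
class AnnotatedDoc:
    doc_id: str
    text: str
    annotations: list[tuple[int, int, str]]  # (start, end, concept_id)


def perturb_corpus(
    docs: Sequence[AnnotatedDoc],
    typo_map: Mapping[str, str | Sequence[str]],
    seed: int = 42,
) -> list[AnnotatedDoc]:
    """Replace mapped canonical tokens inside annotated spans with typos.

    Every word-boundary occurrence of a mapped token within an annotated
    span is replaced (values may be a single typo or a sequence to choose
    from at the given seed); all annotation offsets are recomputed.
    Replacements never cross span boundaries.
    """
    if not typo_map:
        return [AnnotatedDoc(d.doc_id, d.text, list(d.annotations)) for d in docs]
    rng = np.random.default_rng(seed)
    lower_map = {k.lower(): v for k, v in typo_map.items()}
    out: list[AnnotatedDoc] = []
    for doc in docs:
        # collect replacements (start, end, new_text), all inside spans
        repls: list[tuple[int, int, str]] = []
        seen: set[tuple[int, int]] = set()
        for start, end, _cid in sorted(doc.annotations):
            span_text = doc.text[start:end]
            for m in re.finditer(r"[^\W_]+", span_text):
                word = m.group(0).lower()
                if word not in lower_map:
                    continue
                loc = (start + m.start(), start + m.end())
                if loc in seen:  # overlapping annotations share the occurrence
                    continue
                seen.add(loc)
                choice = lower_map[word]
                if not isinstance(choice, str):
                    choice = choice[int(rng.integers(0, len(choice)))]
                repls.append((loc[0], loc[1], choice))
        repls.sort()
        new_text: list[str] = []
        cursor = 0
        # per-annotation offset deltas
        deltas: list[tuple[int, int]] = []  # (original position, cumulative delta)
        delta = 0
        for rstart, rend, replacement in repls:
            new_text.append(doc.text[cursor:rstart])
            new_text.append(replacement)
            delta += len(replacement) - (rend - rstart)
            deltas.append((rend, delta))
            cursor = rend
        new_text.append(doc.text[cursor:])
        text = "".join(new_text)

        def shift(pos: int, *, is_end: bool) -> int:
            d = 0
            for orig, cum in deltas:
                if orig < pos or (is_end and orig <= pos):
                    d = cum
                else:
                    break
            return pos + d

        new_anns = [
            (shift(s, is_end=False), shift(e, is_end=True), cid)
            for s, e, cid in doc.annotations
        ]
        out.append(AnnotatedDoc(doc.doc_id, text, new_anns))
    return out
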