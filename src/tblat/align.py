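"""Token-level alignment score between a candidate and a (noisy) query token.

The candidate (ontology) token drives the positions: for each of its 3-mers,
the index-aligned query 3-mer either has a matrix-backed transition value, or
falls back to a penalty combining the error-category frequency with the
source's identity transition value. Candidate positions with no aligned query
3-mer (length mismatch) contribute 0 — the missing mass is itself the
coverage penalty, since scores are interpreted against the candidate's own
score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from tblat.kmers import (
    ErrorCategory,
    ErrorTypeProfile,
    classify_transition,
    kmers,
    pair_transitions,
)
from tblat.matrix import TransitionMatrix

__all__ = ["AlignmentScore", "align_score", "score_transitions", "frequency_identity_penalty"]


@dataclass(frozen=True)
class AlignmentScore:
    """value: summed transition values and penalties; covered/total: candidate
    3-mer positions with a matrix-backed transition vs. all positions."""

    value: float
    covered: int
    total: int

    @property
    def coverage(self) -> float:
        return self.covered / self.total if self.total else 0.0


def frequency_identity_penalty(
    source: str, target: str, m: TransitionMatrix, profile: ErrorTypeProfile
) -> float:
    """Default penalty for a transition absent from the matrix.

    penalty(s, t) = f(category(s, t)) * id(s), where f is the category's
    relative frequency and id(s) is the identity value m[s][s], falling back
    to the matrix-wide mean identity value when the row lacks one.
    """
    cat = classify_transition(source, target)
    if cat is ErrorCategory.IDENTITY:
        # identity transitions absent from the matrix are still self-evident
        ident = m.identity(source)
        return ident if ident is not None else m.mean_identity()
    ident = m.identity(source)
    if ident is None:
        ident = m.mean_identity()
    return profile.frequency(cat) * ident


PenaltyFn = Callable[[str, str, TransitionMatrix, ErrorTypeProfile], float]


def score_transitions(
    candidate: str,
    targets: Sequence[str | None],
    m: TransitionMatrix,
    profile: ErrorTypeProfile,
    penalty: PenaltyFn = frequency_identity_penalty,
) -> AlignmentScore:
    """Score an explicit per-position transition choice for ``candidate``.

    ``targets[i]`` is the 3-mer the candidate's i-th 3-mer transitions to, or
    None for an uncovered position. Positions whose transition is in the
    matrix add its value; positions with a target but no matrix entry add the
    penalty; None positions add 0 and are not covered.
    """
    sources = kmers(candidate).kmers
    if len(targets) != len(sources):
        raise ValueError(
            f"expected {len(sources)} targets for candidate {candidate!r}, got {len(targets)}"
        )
    value = 0.0
    covered = 0
    for source, target in zip(sources, targets):
        if target is None:
            continue
        stored = m.get(source, target)
        if stored is not None:
            value += stored
            covered += 1
        else:
            value += penalty(source, target, m, profile)
    return AlignmentScore(value, covered, len(sources))


def align_score(
    candidate: str,
    query: str,
    m: TransitionMatrix,
    profile: ErrorTypeProfile,
    penalty: PenaltyFn = frequency_identity_penalty,
) -> AlignmentScore:
    """Alignment score of ``query`` against ``candidate`` (both length >= 3)."""
    alignment = pair_transitions(candidate, query)
    return score_transitions(
        candidate, [rec.target for rec in alignment], m, profile, penalty
    )
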