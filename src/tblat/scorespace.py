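"""Per-token score distributions, percentile lookup and length-aware cut-offs.

For a token, the attainable alignment scores are all sums obtained by
choosing one stored transition value per 3-mer position (multiset
semantics: every combination counts once). When the combination count
exceeds a limit, the space is sampled uniformly at a fixed seed with the
exact extremes appended. A score is interpreted by its percentile within
the token's own distribution; a length-indexed policy maps token length to
the target percentile whose smallest attaining score is the cut-off.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from tblat.errors import DegenerateScoreSpaceError, PolicyError
from tblat.kmers import kmers
from tblat.matrix import TransitionMatrix

__all__ = [
    "ScoreSpace",
    "ScoreSpaceMethod",
    "CutoffPolicy",
    "ScoreSpaceCache",
    "build_score_space",
    "percentile_of",
    "cutoff_score",
]

DEFAULT_ENUM_LIMIT = 10**6
DEFAULT_SAMPLE_SEED = 20220201


class ScoreSpaceMethod(enum.Enum):
    EXACT_ENUM = "exact_enum"
    SAMPLED = "sampled"


@dataclass(frozen=True)
class ScoreSpace:
    """The distribution of attainable alignment scores for one token."""

    token: str
    scores: np.ndarray  # sorted ascending
    min: float
    max: float
    method: ScoreSpaceMethod
    degenerate: bool = False  # no token 3-mer is a matrix source
    seed: int | None = None  # sampling seed, SAMPLED only

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CutoffPolicy:
    """Token length -> target percentile in (0, 100].

    Lengths below ``fuzzy_min_len`` have no percentile: such tokens are
    matched exactly or not at all. Lengths at or above ``long_len`` use
    ``default_percentile``.
    """

    by_length: Mapping[int, float] = field(
        default_factory=lambda: {5: 40.0, 6: 40.0, 7: 40.0, 8: 40.0, 9: 55.0}
    )
    default_percentile: float = 70.0
    long_len: int = 10
    fuzzy_min_len: int = 5

    def __post_init__(self) -> None:
        for length, pct in self.by_length.items():
            if not 0 < pct <= 100:
                raise ValueError(f"percentile {pct} for length {length} outside (0, 100]")
        if not 0 < self.default_percentile <= 100:
            raise ValueError("default percentile outside (0, 100]")

    def percentile_for(self, length: int) -> float | None:
        """Target percentile for a token length; None means exact-match only."""
        if length < self.fuzzy_min_len:
            return None
        if length in self.by_length:
            return self.by_length[length]
        if length >= self.long_len:
            return self.default_percentile
        return self.default_percentile


def _rows_for(token: str, m: TransitionMatrix) -> list[list[float]]:
    # a 3-mer absent as a matrix source contributes the single value 0.0
    rows = []
    for km in kmers(token).kmers:
        row = list(m.row(km).values())
        rows.append(row if row else [0.0])
    return rows


def build_score_space(
    token: str,
    m: TransitionMatrix,
    limit: int = DEFAULT_ENUM_LIMIT,
    seed: int = DEFAULT_SAMPLE_SEED,
) -> ScoreSpace:
    """Enumerate (or sample) the attainable score sums for ``token``.

    Exact enumeration when the cartesian product of row sizes is at most
    ``limit``; otherwise ``limit`` uniform samples at ``seed`` plus the exact
    min and max. A token with no 3-mer among the matrix sources yields a
    degenerate space (min = max = 0), flagged as such.
    """
    rows = _rows_for(token, m)
    degenerate = all(km not in m for km in kmers(token).kmers)
    lo = float(sum(min(r) for r in rows))
    hi = float(sum(max(r) for r in rows))
    n_comb = math.prod(len(r) for r in rows)
    if n_comb <= limit:
        scores = np.zeros(1)
        for r in rows:
            scores = np.add.outer(scores, np.asarray(r, dtype=float)).ravel()
        scores.sort()
        return ScoreSpace(token, scores, lo, hi, ScoreSpaceMethod.EXACT_ENUM, degenerate)
    rng = np.random.default_rng(seed)
    total = np.zeros(limit)
    for r in rows:
        arr = np.asarray(r, dtype=float)
        total += arr[rng.integers(0, len(arr), size=limit)]
    scores = np.concatenate([total, [lo, hi]])
    scores.sort()
    return ScoreSpace(token, scores, lo, hi, ScoreSpaceMethod.SAMPLED, degenerate, seed)


def percentile_of(score: float, space: ScoreSpace) -> float:
    """100 x fraction of stored scores <= ``score`` (empirical step function)."""
    if space.degenerate:
        raise DegenerateScoreSpaceError(
            f"token {space.token!r} has no 3-mer in the matrix; percentile undefined"
        )
    n = len(space.scores)
    # tiny epsilon absorbs float noise from summing in a different order
    rank = np.searchsorted(space.scores, score + 1e-12, side="right")
    return 100.0 * float(rank) / n


def cutoff_score(token: str, space: ScoreSpace, policy: CutoffPolicy) -> float:
    """Smallest stored score whose percentile reaches the policy's target."""
    pct = policy.percentile_for(len(token))
    if pct is None:
        raise PolicyError(
            f"policy defines no percentile for length {len(token)} (exact match only)"
        )
    if space.degenerate:
        raise DegenerateScoreSpaceError(
            f"token {space.token!r} has a degenerate score space"
        )
    n = len(space.scores)
    idx = max(0, math.ceil(n * pct / 100.0) - 1)
    return float(space.scores[idx])


class ScoreSpaceCache:
    """Lazily built per-token score spaces over one matrix.

    Spaces are query-independent, so a lexicon's worth can be precomputed
    once and reused for every annotation call; ``save``/``load`` persist a
    compact per-token record (min, max, method and a 1%-step quantile grid).
    Loaded caches answer percentile queries from the grid.
    """

    _GRID = np.arange(1, 101)  # percentile steps

    def __init__(
        self,
        m: TransitionMatrix,
        limit: int = DEFAULT_ENUM_LIMIT,
        seed: int = DEFAULT_SAMPLE_SEED,
    ):
        self.matrix = m
        self.limit = limit
        self.seed = seed
        self._spaces: dict[str, ScoreSpace] = {}

    def get(self, token: str) -> ScoreSpace:
        if token not in self._spaces:
            self._spaces[token] = build_score_space(
                token, self.matrix, limit=self.limit, seed=self.seed
            )
        return self._spaces[token]

    def precompute(self, tokens) -> None:
        for token in tokens:
            self.get(token)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# score-space cache; quantile grid at 1% steps\n")
            for token in sorted(self._spaces):
                sp = self._spaces[token]
                if sp.degenerate:
                    fh.write(f"{token}\tdegenerate\t0\t0\t\n")
                    continue
                grid = np.quantile(sp.scores, self._GRID / 100.0)
                grid_s = ",".join(f"{g:.6f}" for g in grid)
                fh.write(
                    f"{token}\t{sp.method.value}\t{sp.min:.6f}\t{sp.max:.6f}\t{grid_s}\n"
                )

    @staticmethod
    def load(path: str | Path) -> dict[str, ScoreSpace]:
        """Read cached spaces; each token's grid stands in for its scores."""
        spaces: dict[str, ScoreSpace] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            token, method, lo, hi, grid_s = (line.split("\t") + [""])[:5]
            if method == "degenerate":
                spaces[token] = ScoreSpace(
                    token, np.zeros(1), 0.0, 0.0, ScoreSpaceMethod.EXACT_ENUM, True
                )
                continue
            grid = np.array([float(x) for x in grid_s.split(",")])
            spaces[token] = ScoreSpace(
                token, grid, float(lo), float(hi), ScoreSpaceMethod(method)
            )
        return spaces
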