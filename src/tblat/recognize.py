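"""Entity linkage: map candidate text spans to ontology concepts.

Span tokens resolve to ontology tokens — exact string equality first, then
the fuzzy path: 3-mer seeded candidate retrieval, alignment scoring, and a
percentile cut-off in each candidate's own score distribution. A concept is
returned when all content tokens of at least one of its labels/synonyms are
covered by distinct resolved span tokens, order-insensitively.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from tblat.align import align_score
from tblat.kmers import ErrorTypeProfile
from tblat.lexicon import OntologyLexicon, candidates_for
from tblat.matrix import TransitionMatrix
from tblat.scorespace import CutoffPolicy, ScoreSpaceCache, cutoff_score, percentile_of
from tblat.textprep import StopWordList, Token, content_tokens, default_stopwords

__all__ = ["Annotation", "MatchType", "ResolvedToken", "Recognizer"]

EXACT = "EXACT"
FUZZY = "FUZZY"
MatchType = str

_SENTENCE_RE = re.compile(r"[^.!?\n]+[.!?]?")


@dataclass(frozen=True)
class Annotation:
    doc_id: str
    start: int
    end: int
    concept_id: str
    match_type: MatchType
    score: float  # mean per-token percentile, 0..100
    matched_text: str = ""


@dataclass(frozen=True)
class ResolvedToken:
    """A span token resolved against the ontology vocabulary."""

    query: str
    matched: str | None  # ontology token, or None if unresolvable
    percentile: float  # 100 for exact matches
    exact: bool


@dataclass(frozen=True)
class _ConceptHit:
    concept_id: str
    phrase_size: int
    score: float
    exact: bool


class Recognizer:
    """Bundles lexicon, matrix, score-space cache and cut-off policy.

    ``min_token_len`` controls span-side cleansing; it defaults to 3 so that
    short but meaningful vocabulary words (e.g. "hip") survive, matched
    exactly per the cut-off policy.
    """

    def __init__(
        self,
        lexicon: OntologyLexicon,
        matrix: TransitionMatrix,
        profile: ErrorTypeProfile | None = None,
        policy: CutoffPolicy | None = None,
        spaces: ScoreSpaceCache | None = None,
        stoplist: StopWordList | None = None,
        min_token_len: int = 3,
        window: int = 6,
    ):
        self.lexicon = lexicon
        self.matrix = matrix
        self.profile = profile if profile is not None else ErrorTypeProfile.default()
        self.policy = policy if policy is not None else CutoffPolicy()
        self.spaces = spaces if spaces is not None else ScoreSpaceCache(matrix)
        self.stoplist = stoplist if stoplist is not None else default_stopwords()
        self.min_token_len = min_token_len
        self.window = window

    # -- token resolution ---------------------------------------------------

    def resolve_token(self, query: str) -> ResolvedToken:
        """Resolve one span token to an ontology token, or fail."""
        if query in self.lexicon.token_index:
            return ResolvedToken(query, query, 100.0, True)
        if len(query) < 3:
            return ResolvedToken(query, None, 0.0, False)
        best: tuple[tuple, str, float] | None = None  # (order key, token, percentile)
        for cand in candidates_for(query, self.lexicon):
            pct_target = self.policy.percentile_for(len(cand))
            if pct_target is None:
                continue  # short vocabulary tokens match exactly only
            space = self.spaces.get(cand)
            if space.degenerate:
                continue
            result = align_score(cand, query, self.matrix, self.profile)
            if result.value < cutoff_score(cand, space, self.policy):
                continue
            pct = percentile_of(result.value, space)
            key = (pct, result.value, _rev(cand))
            if best is None or key > best[0]:
                best = (key, cand, pct)
        if best is None:
            return ResolvedToken(query, None, 0.0, False)
        return ResolvedToken(query, best[1], best[2], False)

    # -- span linkage -------------------------------------------------------

    def _link_resolved(self, resolved: Sequence[ResolvedToken]) -> _ConceptHit | None:
        by_token: dict[str, list[ResolvedToken]] = {}
        for r in resolved:
            if r.matched is not None:
                by_token.setdefault(r.matched, []).append(r)
        if not by_token:
            return None
        available = Counter({tok: len(rs) for tok, rs in by_token.items()})
        candidates: set[str] = set()
        for tok in by_token:
            candidates |= self.lexicon.token_index.get(tok, set())
        best: _ConceptHit | None = None
        for cid in sorted(candidates):
            for phrase in self.lexicon.concepts[cid]:
                need = phrase.counter
                if any(available[tok] < n for tok, n in need.items()):
                    continue
                used: list[ResolvedToken] = []
                for tok, n in need.items():
                    picks = sorted(by_token[tok], key=lambda r: -r.percentile)[:n]
                    used.extend(picks)
                score = sum(r.percentile for r in used) / len(used)
                hit = _ConceptHit(cid, len(phrase.tokens), score, all(r.exact for r in used))
                if best is None or (hit.score, hit.phrase_size, _rev(cid)) > (
                    best.score, best.phrase_size, _rev(best.concept_id)
                ):
                    best = hit
        return best

    def link_span(self, span_text: str) -> Annotation | None:
        """Best-matching concept for a candidate span, or None."""
        toks = content_tokens(span_text, self.stoplist, min_len=self.min_token_len)
        if not toks:
            return None
        resolved = [self.resolve_token(t.surface) for t in toks]
        hit = self._link_resolved(resolved)
        if hit is None:
            return None
        return Annotation(
            doc_id="",
            start=0,
            end=len(span_text),
            concept_id=hit.concept_id,
            match_type=EXACT if hit.exact else FUZZY,
            score=hit.score,
            matched_text=span_text,
        )

    def exact_match(self, span_text: str) -> Annotation | None:
        """Baseline linkage using string equality only (case-insensitive)."""
        toks = content_tokens(span_text, self.stoplist, min_len=self.min_token_len)
        if not toks:
            return None
        resolved = [
            ResolvedToken(t.surface, t.surface, 100.0, True)
            if t.surface in self.lexicon.token_index
            else ResolvedToken(t.surface, None, 0.0, False)
            for t in toks
        ]
        hit = self._link_resolved(resolved)
        if hit is None:
            return None
        return Annotation("", 0, len(span_text), hit.concept_id, EXACT, hit.score, span_text)

    # -- full-text annotation ----------------------------------------------

    def annotate(self, text: str, doc_id: str = "") -> list[Annotation]:
        """Sliding-window annotation over sentences; longest match wins.

        Boundary detection is a plumbing convenience: windows of 1..window
        contiguous content tokens per sentence are offered for linkage and
        overlapping hits are resolved longest-first.
        """
        hits: list[tuple[int, Annotation]] = []
        for sent in _SENTENCE_RE.finditer(text):
            toks = content_tokens(sent.group(0), self.stoplist, min_len=self.min_token_len)
            offset = sent.start()
            abs_toks = [Token(t.surface, t.start + offset, t.end + offset) for t in toks]
            for width in range(min(self.window, len(abs_toks)), 0, -1):
                for i in range(len(abs_toks) - width + 1):
                    window = abs_toks[i : i + width]
                    resolved = [self.resolve_token(t.surface) for t in window]
                    if any(r.matched is None for r in resolved):
                        continue
                    hit = self._link_resolved(resolved)
                    # the matched phrase must account for the whole window,
                    # otherwise a shorter window already reports this hit
                    if hit is None or hit.phrase_size != width:
                        continue
                    start, end = window[0].start, window[-1].end
                    hits.append(
                        (
                            width,
                            Annotation(
                                doc_id, start, end, hit.concept_id,
                                EXACT if hit.exact else FUZZY, hit.score,
                                text[start:end],
                            ),
                        )
                    )
        hits.sort(key=lambda wa: (-wa[0], wa[1].start, -wa[1].score))
        chosen: list[Annotation] = []
        for _, ann in hits:
            if all(ann.end <= c.start or ann.start >= c.end for c in chosen):
                chosen.append(ann)
        chosen.sort(key=lambda a: a.start)
        return chosen


def _rev(s: str) -> tuple:
    # sort key that makes the lexicographically *smallest* id win in max()
    return tuple(-ord(c) for c in s)
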