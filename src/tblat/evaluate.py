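"""Precision / recall / F1 scoring of predicted vs. gold annotations.

Counts are micro-aggregated across documents. MENTION mode matches on
(document, span, concept); DOCUMENT_SET mode compares per-document concept
sets. Concept IDs are compared after alt_id resolution, and an optional
root filter restricts both sides to a subtree before counting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from tblat.lexicon import OntologyLexicon
from tblat.recognize import Annotation

__all__ = ["EvalMode", "EvalReport", "evaluate", "read_gold_tsv", "write_annotations_tsv"]


class EvalMode(enum.Enum):
    MENTION = "mention"
    DOCUMENT_SET = "document_set"


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        """Counts plus metrics on the percent scale."""
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": round(100 * self.precision, 2),
            "recall": round(100 * self.recall, 2),
            "f1": round(100 * self.f1, 2),
        }


def _normalize(
    anns: Iterable[Annotation],
    lexicon: OntologyLexicon | None,
    root_concepts: set[str] | None,
) -> list[Annotation]:
    out = []
    for a in anns:
        cid = lexicon.resolve_id(a.concept_id) if lexicon is not None else a.concept_id
        if root_concepts is not None and cid not in root_concepts:
            continue
        out.append(Annotation(a.doc_id, a.start, a.end, cid, a.match_type, a.score))
    return out


def evaluate(
    pred: Sequence[Annotation],
    gold: Sequence[Annotation],
    mode: EvalMode = EvalMode.MENTION,
    lexicon: OntologyLexicon | None = None,
    docs: Iterable[str] | None = None,
) -> EvalReport:
    """Micro-averaged precision/recall/F1 of ``pred`` against ``gold``.

    With ``docs`` given, any annotation referencing a document outside that
    set raises ValueError. A lexicon with a root filter restricts both sides
    to the filtered subtree and resolves retired IDs first.
    """
    root_concepts = None
    if lexicon is not None and lexicon.root_filter is not None:
        root_concepts = set(lexicon.concepts)
    pred_n = _normalize(pred, lexicon, root_concepts)
    gold_n = _normalize(gold, lexicon, root_concepts)
    if docs is not None:
        allowed = set(docs)
        for a in [*pred_n, *gold_n]:
            if a.doc_id not in allowed:
                raise ValueError(f"annotation references unknown document {a.doc_id!r}")
    if mode is EvalMode.MENTION:
        pred_keys = [(a.doc_id, a.start, a.end, a.concept_id) for a in pred_n]
        gold_keys = [(a.doc_id, a.start, a.end, a.concept_id) for a in gold_n]
    elif mode is EvalMode.DOCUMENT_SET:
        pred_keys = sorted({(a.doc_id, a.concept_id) for a in pred_n})
        gold_keys = sorted({(a.doc_id, a.concept_id) for a in gold_n})
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown mode {mode}")
    remaining = list(gold_keys)
    tp = 0
    for key in pred_keys:
        if key in remaining:
            remaining.remove(key)
            tp += 1
    fp = len(pred_keys) - tp
    fn = len(remaining)
    return EvalReport(tp, fp, fn)


def read_gold_tsv(path: str | Path) -> list[Annotation]:
    """Read annotations from TSV.

    Accepts the 4-column gold format ``doc_id, start, end, concept_id`` and
    the 7-column output of :func:`write_annotations_tsv` (``doc_id, start,
    end, matched_text, concept_id, match_type, score``).
    """
    anns = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        doc_id, start, end = cols[0], int(cols[1]), int(cols[2])
        if len(cols) >= 7:
            text, cid, mtype, score = cols[3], cols[4], cols[5], float(cols[6])
            anns.append(Annotation(doc_id, start, end, cid, mtype, score, text))
        else:
            anns.append(Annotation(doc_id, start, end, cols[3], "EXACT", 100.0))
    return anns


def write_annotations_tsv(anns: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# doc_id\tstart\tend\tmatched_text\tconcept_id\tmatch_type\tscore\n")
        for a in anns:
            fh.write(
                f"{a.doc_id}\t{a.start}\t{a.end}\t{a.matched_text}\t"
                f"{a.concept_id}\t{a.match_type}\t{a.score:.2f}\n"
            )
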