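"""Strict entity- and relation-level precision / recall / F1.

A predicted entity is a true positive only if an as-yet-unmatched gold
span has exactly the same (start, end, label) — strict matching, with
one-to-one greedy pairing in document order. A predicted relation is a
true positive only if the gold document contains a relation whose head
span, tail span (boundaries and entity label) and relation label all
match exactly.

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)

Zero denominators yield 0 by convention. The headline numbers are
micro-averaged (counts pooled over labels and documents); per-label
breakdowns are reported alongside. A relaxed overlap-based entity
matching mode exists behind a flag for error analysis, but all headline
metrics are strict.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import AnnotatedDocument, EntitySpan

__all__ = [
    "ConfusionCounts",
    "match_entities",
    "match_relations",
    "precision",
    "recall",
    "f1",
    "evaluate",
]


@dataclass
class ConfusionCounts:
    """TP/FP/FN accumulators, micro-aggregated and per label."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_label: dict[str, "ConfusionCounts"] = field(default_factory=dict)

    def add(self, label: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        self.tp += tp
        self.fp += fp
        self.fn += fn
        bucket = self.per_label.setdefault(label, ConfusionCounts())
        bucket.tp += tp
        bucket.fp += fp
        bucket.fn += fn

    def merge(self, other: "ConfusionCounts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        for label, counts in other.per_label.items():
            bucket = self.per_label.setdefault(label, ConfusionCounts())
            bucket.tp += counts.tp
            bucket.fp += counts.fp
            bucket.fn += counts.fn


def _span_key(span: EntitySpan) -> tuple[int, int, str]:
    return (span.start, span.end, span.label)


def match_entities(
    gold: Sequence[EntitySpan],
    pred: Sequence[EntitySpan],
    overlap: bool = False,
) -> ConfusionCounts:
    """One-to-one greedy matching of predictions against gold spans.

    Strict mode requires identical (start, end, label). Relaxed mode
    (``overlap=True``) accepts any boundary overlap with matching label.
    """
    counts = ConfusionCounts()
    unmatched = list(gold)
    for p in pred:
        hit = None
        for g in unmatched:
            if overlap:
                ok = g.label == p.label and g.start < p.end and p.start < g.end
            else:
                ok = _span_key(g) == _span_key(p)
            if ok:
                hit = g
                break
        if hit is not None:
            unmatched.remove(hit)
            counts.add(p.label, tp=1)
        else:
            counts.add(p.label, fp=1)
    for g in unmatched:
        counts.add(g.label, fn=1)
    return counts


def _relation_key(doc: AnnotatedDocument, rel) -> tuple:
    head = doc.entity_by_id(rel.head)
    tail = doc.entity_by_id(rel.tail)
    return (_span_key(head), _span_key(tail), rel.label)


def match_relations(
    gold_docs: Sequence[AnnotatedDocument],
    pred_docs: Sequence[AnnotatedDocument],
) -> ConfusionCounts:
    """Strict relation matching over aligned corpora (multiset semantics)."""
    if len(gold_docs) != len(pred_docs):
        raise ValueError(
            f"corpora misaligned: {len(gold_docs)} gold vs {len(pred_docs)} "
            "predicted documents"
        )
    counts = ConfusionCounts()
    for gold_doc, pred_doc in zip(gold_docs, pred_docs):
        if gold_doc.tokens != pred_doc.tokens:
            raise ValueError("corpora misaligned: token sequences differ")
        gold_keys = Counter(_relation_key(gold_doc, r) for r in gold_doc.relations)
        for rel in pred_doc.relations:
            key = _relation_key(pred_doc, rel)
            if gold_keys[key] > 0:
                gold_keys[key] -= 1
                counts.add(rel.label, tp=1)
            else:
                counts.add(rel.label, fp=1)
        for key, remaining in gold_keys.items():
            if remaining > 0:
                counts.add(key[2], fn=remaining)
    return counts


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def _prf_block(counts: ConfusionCounts) -> dict:
    p, r = precision(counts), recall(counts)
    return {
        "precision": p,
        "recall": r,
        "f1": f1(p, r),
        "precision_pct": round(100.0 * p, 2),
        "recall_pct": round(100.0 * r, 2),
        "f1_pct": round(100.0 * f1(p, r), 2),
        "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn},
    }


def _task_report(counts: ConfusionCounts) -> dict:
    return {
        "micro": _prf_block(counts),
        "per_label": {
            label: _prf_block(sub) for label, sub in sorted(counts.per_label.items())
        },
    }


def evaluate(
    gold_docs: Sequence[AnnotatedDocument],
    pred_docs: Sequence[AnnotatedDocument],
) -> dict:
    """Micro and per-label P/R/F1 for entities and relations, as a dict."""
    if len(gold_docs) != len(pred_docs):
        raise ValueError("corpora misaligned: document counts differ")
    entity_counts = ConfusionCounts()
    for gold_doc, pred_doc in zip(gold_docs, pred_docs):
        if gold_doc.tokens != pred_doc.tokens:
            raise ValueError("corpora misaligned: token sequences differ")
        entity_counts.merge(match_entities(gold_doc.entities, pred_doc.entities))
    relation_counts = match_relations(gold_docs, pred_docs)
    return {"ner": _task_report(entity_counts), "re": _task_report(relation_counts)}
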