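"""Span-level scoring of predicted quotations against gold annotations.

A predicted span is a true positive only when its (start, end) offsets
exactly equal a gold span — the strictest, fully reproducible matching
criterion.  Metrics follow the usual span-extraction conventions:

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F         = harmonic mean of precision and recall
    accuracy  = tp / (tp + fp + fn)      (a Jaccard-style agreement)

Aggregation over a corpus is micro-averaged: counts are pooled across
documents before the ratios are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

Span = tuple[int, int]

__all__ = ["GoldDocument", "EvalReport", "match_spans", "compute_metrics", "evaluate_corpus"]


@dataclass(frozen=True)
class GoldDocument:
    """Gold quotation annotations for one document."""

    doc_id: str
    spans: tuple[Span, ...]

    def __post_init__(self) -> None:
        _validate_spans(self.spans, "gold")


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    accuracy: float
    degenerate: bool = False
    per_category: Mapping[str, "EvalReport"] = field(default_factory=dict)


def _validate_spans(spans: Sequence[Span], label: str) -> None:
    prev_end = -1
    for start, end in spans:
        if start >= end:
            raise ValueError(f"{label} span ({start}, {end}) is empty or reversed")
        if start < prev_end:
            raise ValueError(f"{label} spans overlap or are unsorted at ({start}, {end})")
        prev_end = end


def match_spans(predicted: Sequence[Span], gold: Sequence[Span]) -> tuple[int, int, int]:
    """Exact-offset matching of predicted against gold spans.

    Returns (tp, fp, fn).  Each gold span matches at most one prediction;
    inputs must be sorted and non-overlapping.
    """
    pred = [tuple(s) for s in predicted]
    gld = [tuple(s) for s in gold]
    _validate_spans(pred, "predicted")
    _validate_spans(gld, "gold")
    gold_set = set(gld)
    tp = sum(1 for s in pred if s in gold_set)
    fp = len(pred) - tp
    fn = len(gld) - tp
    return tp, fp, fn


def compute_metrics(tp: int, fp: int, fn: int, per_category: Mapping[str, EvalReport] | None = None) -> EvalReport:
    """Precision, recall, F score and accuracy from pooled match counts.

    With no spans at all (tp=fp=fn=0) every metric is reported as 1.0
    with the ``degenerate`` flag set.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        return EvalReport(0, 0, 0, 1.0, 1.0, 1.0, 1.0, degenerate=True, per_category=per_category or {})
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f_score = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = tp / (tp + fp + fn)
    return EvalReport(tp, fp, fn, precision, recall, f_score, accuracy, per_category=per_category or {})


def evaluate_corpus(
    predicted: Mapping[str, Sequence[Span]],
    gold: Mapping[str, Sequence[Span]],
    categories: Mapping[str, str] | None = None,
) -> EvalReport:
    """Micro-averaged corpus evaluation.

    ``predicted`` and ``gold`` map doc_id -> span list; documents missing
    from one side contribute an empty span list there.  ``categories``
    optionally maps doc_id to a stratum label for a per-category
    breakdown (each stratum scored by the same pooled-count rule).
    """
    doc_ids = sorted(set(predicted) | set(gold))
    totals = [0, 0, 0]
    by_cat: dict[str, list[int]] = {}
    for doc_id in doc_ids:
        tp, fp, fn = match_spans(predicted.get(doc_id, ()), gold.get(doc_id, ()))
        for i, v in enumerate((tp, fp, fn)):
            totals[i] += v
        if categories is not None:
            cat = categories.get(doc_id, "uncategorised")
            acc = by_cat.setdefault(cat, [0, 0, 0])
            for i, v in enumerate((tp, fp, fn)):
                acc[i] += v
    per_category = {cat: compute_metrics(*counts) for cat, counts in sorted(by_cat.items())}
    return compute_metrics(*totals, per_category=per_category)
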