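"""Scoring of annotation transfer against a reference annotation.

Used for re-annotation experiments: predict subsystems for genes that
already carry curated annotations, then count per gene

* TP — a prediction exists and matches the reference annotation,
* FP — a prediction exists but does not match,
* FN — the gene carries reference annotation but got no prediction,

over the evaluation universe of genes having at least one reference
subsystem.  Precision is TP/(TP+FP) and coverage is TP/(TP+FN).

Two match rules are offered because a gene can belong to several
subsystems: the lenient rule (default) accepts any overlap between the
predicted and reference subsystem sets; ``strict`` requires exact set
equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotation import AnnotationSet
from .homology import MappingResult

__all__ = [
    "EvaluationCounts",
    "UndefinedRatioError",
    "compare_annotations",
    "precision",
    "coverage",
]


class UndefinedRatioError(ZeroDivisionError):
    """A precision/coverage denominator is zero; the ratio is undefined
    (distinct from being 0)."""


@dataclass(frozen=True)
class EvaluationCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError(f"counts must be non-negative: {self}")


def compare_annotations(
    reference: AnnotationSet,
    predicted: Sequence[MappingResult],
    strict: bool = False,
) -> EvaluationCounts:
    """Count TP/FP/FN of predictions against a reference annotation.

    Predictions are matched to reference genes by query id value; genes
    without reference annotation are ignored, and predictions for such
    genes do not count either way.
    """
    if not reference.mapping:
        raise ValueError("reference annotation is empty")
    by_query: dict[str, frozenset[str]] = {}
    for r in predicted:
        if r.mapped:
            by_query[r.query.value] = r.subsystems
    tp = fp = fn = 0
    for gene, ref_subs in reference.mapping.items():
        pred_subs = by_query.get(gene)
        if pred_subs is None:
            fn += 1
        elif (pred_subs == ref_subs) if strict else bool(pred_subs & ref_subs):
            tp += 1
        else:
            fp += 1
    return EvaluationCounts(TP=tp, FP=fp, FN=fn)


def precision(c: EvaluationCounts) -> float:
    """TP / (TP + FP); raises when no predictions were scored."""
    if c.TP + c.FP == 0:
        raise UndefinedRatioError("precision undefined: no scored predictions (TP+FP=0)")
    return c.TP / (c.TP + c.FP)


def coverage(c: EvaluationCounts) -> float:
    """TP / (TP + FN); raises when no reference genes were scored."""
    if c.TP + c.FN == 0:
        raise UndefinedRatioError("coverage undefined: no reference genes scored (TP+FN=0)")
    return c.TP / (c.TP + c.FN)
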