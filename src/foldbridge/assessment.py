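"""Benchmark harness: per-query confusion counts and summary metrics.

For a query of known fold, every retrieved candidate (best domain per
target sequence) is scored against the filtering thresholds: true-fold
candidates that pass are true positives, true-fold candidates that fail
are false negatives, other-fold candidates that pass are false
positives, and other-fold candidates that fail are true negatives.
Candidates never retrieved at any E-value are not counted, so the
true-negative pool is search-scoped.  The four per-query metrics —
sensitivity, specificity, precision (as percentages) and the Matthews
correlation coefficient — are summarized across families by their
component-wise medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fold_assignment import DEFAULT_EVALUE_MAX, DEFAULT_MIN_QUERY_COV
from .io_formats import DataError, FoldMap, HitTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Percent-scale classification metrics; ``None`` marks an undefined
    component (zero denominator), which is distinct from zero."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    mcc: float | None


def confusion_from_hits(
    all_hits: HitTable,
    foldmap: FoldMap,
    true_fold: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
) -> ConfusionCounts:
    """Count TP/FN/FP/TN over the retrieved candidates of one query."""
    if not true_fold:
        raise DataError("true_fold must be a non-empty fold id")
    tp = fp = tn = fn = 0
    for h in all_hits.best_domain_per_target():
        fold = foldmap.fold_of(h.target_id)
        passes = h.evalue < evalue_max and h.query_coverage > min_query_cov
        if fold == true_fold:
            if passes:
                tp += 1
            else:
                fn += 1
        else:
            if passes:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Evaluate the four metric formulas exactly; zero denominators flag
    the component undefined rather than coercing it to zero."""
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    prec = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn) * (c.tn + c.fp)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else None
    )
    return Metrics(sensitivity=sens, specificity=spec, precision=prec, mcc=mcc)


def _median(values: list[float]) -> float | None:
    if not values:
        return None
    values = sorted(values)
    n = len(values)
    mid = n // 2
    return values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])


def success_rate(correct_assigned: int, total_assigned: int) -> float:
    """Percentage of assigned families whose fold call is correct."""
    if total_assigned <= 0:
        raise DataError("no assigned families")
    return 100.0 * correct_assigned / total_assigned


def summarize(
    per_family: list[Metrics],
    correct_assigned: int | None = None,
    total_assigned: int | None = None,
) -> dict:
    """Component-wise medians across families (undefined entries ignored),
    optionally with the overall success rate."""
    if not per_family:
        raise DataError("summarize requires at least one scored family")
    out = {
        "median_sensitivity": _median(
            [m.sensitivity for m in per_family if m.sensitivity is not None]
        ),
        "median_specificity": _median(
            [m.specificity for m in per_family if m.specificity is not None]
        ),
        "median_precision": _median(
            [m.precision for m in per_family if m.precision is not None]
        ),
        "median_mcc": _median([m.mcc for m in per_family if m.mcc is not None]),
        "n_families": len(per_family),
    }
    if correct_assigned is not None and total_assigned is not None:
        out["success_rate"] = success_rate(correct_assigned, total_assigned)
    return out
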