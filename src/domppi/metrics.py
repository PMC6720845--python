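"""Confusion-matrix metrics and ROC/AUC.

All ratio metrics are computed with exact rational arithmetic and only
converted to floating point at the end; percentages are rounded half-up at
the presentation layer, never internally.

Note: the F1 formula used here is the literal 2*TP / (2*TP + FP + FN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary prediction run."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("at least one prediction is required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percentage-scale metrics; ``None`` marks an undefined value."""

    acc: float | None
    sn: float | None
    spe: float | None
    pre: float | None
    f1: float | None
    mcc: float | None
    fn_rate: float | None
    fp_rate: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "acc": self.acc,
            "sn": self.sn,
            "spe": self.spe,
            "pre": self.pre,
            "f1": self.f1,
            "mcc": self.mcc,
            "fn_rate": self.fn_rate,
            "fp_rate": self.fp_rate,
        }


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation only)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return float(100 * Fraction(num, den))


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """The six standard measurements plus fn/fp rates, as percentages.

    MCC uses the denominator sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)); any zero
    factor makes MCC undefined (reported as None with a warning).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = _ratio(tp + tn, counts.total, "accuracy")
    sn = _ratio(tp, tp + fn, "sensitivity")
    spe = _ratio(tn, tn + fp, "specificity")
    pre = _ratio(tp, tp + fp, "precision")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    denom_sq = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom_sq == 0:
        warnings.warn("MCC undefined: zero denominator", stacklevel=2)
        mcc = None
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(denom_sq)
    fn_rate = _ratio(fn, fn + tp, "fn rate")
    fp_rate = _ratio(fp, fp + tn, "fp rate")
    return MetricReport(
        acc=acc, sn=sn, spe=spe, pre=pre, f1=f1, mcc=mcc,
        fn_rate=fn_rate, fp_rate=fp_rate,
    )


def fn_fp_rates(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(100*FN/(FN+TP), 100*FP/(FP+TN)); the complements of SN and SPE."""
    return (
        _ratio(counts.fn, counts.fn + counts.tp, "fn rate"),
        _ratio(counts.fp, counts.fp + counts.tn, "fp rate"),
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Build counts from parallel 0/1 label arrays."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must have identical shape")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoidal AUC plus the ROC point list (FPR, TPR).

    Tied scores are handled by the threshold sweep, which makes the result
    equal to the Mann–Whitney pairwise-ordering statistic with half credit
    for ties.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have identical shape")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))
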