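"""Confusion counting and the four binary performance metrics.

Counts follow the N+/N- bookkeeping: the totals of positive and negative
sequences plus the two error counts (false negatives and false positives).
Sensitivity, specificity and accuracy are the usual complements of the error
rates; the correlation coefficient is the standard Matthews formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics", "counts_from_predictions"]


@dataclass(frozen=True)
class ConfusionCounts:
    """N+ (positives), N- (negatives), false negatives, false positives."""

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_pos and 0 <= self.fp <= self.n_neg):
            raise ValueError("error counts must satisfy 0 <= fn <= n_pos, 0 <= fp <= n_neg")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.n_pos + other.n_pos, self.n_neg + other.n_neg,
            self.fn + other.fn, self.fp + other.fp,
        )

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float

    def as_percent(self) -> dict[str, float]:
        """Acc/Sn/Sp/MCC scaled by 100, the scale used in reported tables."""
        return {
            "acc": 100 * self.acc, "sn": 100 * self.sn,
            "sp": 100 * self.sp, "mcc": 100 * self.mcc,
        }


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    ``Sn = 1 - fn/n_pos``, ``Sp = 1 - fp/n_neg``,
    ``Acc = 1 - (fn+fp)/(n_pos+n_neg)``; MCC is the standard
    confusion-matrix form ``(tp*tn - fp*fn)/sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``
    with MCC defined as 0 when any denominator factor vanishes.  (A commonly
    printed rearrangement with *sum* terms inside the radicand is a
    typographical variant that disagrees for unbalanced counts; the standard
    form is implemented.)
    """
    if c.n_pos <= 0 or c.n_neg <= 0:
        raise ValueError("metrics require n_pos > 0 and n_neg > 0")
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)
    tp, tn = c.tp, c.tn
    denom = (tp + c.fp) * (tp + c.fn) * (tn + c.fp) * (tn + c.fn)
    mcc = 0.0 if denom == 0 else (tp * tn - c.fp * c.fn) / sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Build counts from 0/1 label arrays (1 = positive class)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have identical shape")
    return ConfusionCounts(
        n_pos=int((y_true == 1).sum()),
        n_neg=int((y_true == 0).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
    )
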