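"""Classifier performance metrics.

Conventions: the positive class is the lncRNA. TP is a lncRNA called
lncRNA, TN an mRNA called mRNA, FP an mRNA called lncRNA, FN a lncRNA
called mRNA. The five summary metrics are

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

A metric whose denominator is zero is reported as ``None`` (an explicit
undefined marker), never silently as 0. The ROC curve enumerates the unique
scores in descending order (with a +inf sentinel so the curve starts at
(0, 0)); ties are grouped at a single threshold, and the AUC is the
trapezoidal integral of TPR over FPR — numerically identical to the
Mann-Whitney pairwise statistic with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm

from .labels import LNCRNA, MRNA


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
        }


def _check_labels(labels: Sequence[str]) -> None:
    bad = set(labels) - {LNCRNA, MRNA}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {LNCRNA!r}/{MRNA!r}")


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with lncRNA as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label vectors differ in length")
    _check_labels(true_labels)
    _check_labels(predicted_labels)
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == LNCRNA:
            if p == LNCRNA:
                tp += 1
            else:
                fn += 1
        else:
            if p == LNCRNA:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(cc: ConfusionCounts) -> MetricSet:
    """The five summary metrics; zero-denominator entries come back as None."""
    if cc.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    sens = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else None
    spec = cc.tn / (cc.fp + cc.tn) if (cc.fp + cc.tn) > 0 else None
    acc = (cc.tp + cc.tn) / cc.total
    prec = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) > 0 else None
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricSet(sens, spec, acc, prec, f1)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # descending; first entry is the +inf sentinel
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(map(float, self.fpr), map(float, self.tpr)))


def roc_curve(scores: Sequence[float], true_labels: Sequence[str]) -> RocCurve:
    """ROC over all unique score thresholds plus the trapezoidal AUC.

    Both classes must be present and all scores finite.
    """
    _check_labels(true_labels)
    y = np.array([1 if t == LNCRNA else 0 for t in true_labels])
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thresholds, auc)
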