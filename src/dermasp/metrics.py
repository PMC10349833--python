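"""Confusion-matrix performance measures for the binary lesion task.

Melanoma (label 1) is the positive class throughout: a false negative is a
missed melanoma.  Five measures are derived from the TP/TN/FP/FN counts —
accuracy, precision, recall, F1 and the Matthews correlation coefficient,
the latter being the headline score because superpixel class counts need not
be balanced.  A zero denominator does not raise: the affected measure is
reported as 0.0 and flagged undefined, so batch sweeps never abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


def confusion(y_true, y_pred, positive_class: int = 1) -> ConfusionMatrix:
    """TP/TN/FP/FN counts with melanoma (1) positive by default."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size == 0:
        raise ValueError("need at least one prediction")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 and MCC from one confusion matrix."""
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    tp, tn, fp, fn = float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn)
    undefined: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / cm.total
    precision = ratio("precision", tp, tp + fp)
    recall = ratio("recall", tp, tp + fn)
    f1 = ratio("f1", 2.0 * recall * precision, recall + precision)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio("mcc", tp * tn - fp * fn, mcc_den)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        undefined=tuple(undefined),
    )
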