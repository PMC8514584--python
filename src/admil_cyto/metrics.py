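"""Confusion matrices and the four case-classification metrics.

Malignant is the positive class.  Balanced accuracy — the mean of sensitivity
and specificity — is the headline number because benign and malignant case
counts are unequal.  Display rounding is half-up to three decimals; the
``rounded_inputs`` switch averages the already-rounded sensitivity and
specificity instead of the exact values, which is how such tables are often
assembled in print.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with benign = negative, malignant = positive."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def round3(x: float) -> float:
    """Round half-up to 3 decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float

    def rounded(self) -> "MetricsReport":
        return MetricsReport(*(round3(v) for v in
                               (self.sensitivity, self.specificity,
                                self.accuracy, self.balanced_accuracy)))

    def as_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy, "balanced_accuracy": self.balanced_accuracy}


def compute_metrics(cm: ConfusionMatrix, rounded_inputs: bool = False) -> MetricsReport:
    """Sensitivity, specificity, accuracy and balanced accuracy from counts.

    ``rounded_inputs=True`` computes balanced accuracy from the 3-decimal
    sensitivity/specificity rather than the exact ratios.
    """
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive (malignant) cases; sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no negative (benign) cases; specificity undefined")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    if rounded_inputs:
        bal = (round3(sens) + round3(spec)) / 2.0
    else:
        bal = (sens + spec) / 2.0
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         balanced_accuracy=bal)


def results_to_confusion(results, threshold: float = 0.5) -> ConfusionMatrix:
    """Tabulate case results (objects with true_label and probability) into counts."""
    results = list(results)
    if not results:
        raise ValueError("no case results to tabulate")
    tn = fp = fn = tp = 0
    for r in results:
        pred = 1 if r.probability >= threshold else 0
        if r.true_label == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)
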