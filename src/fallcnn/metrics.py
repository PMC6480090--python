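"""Binary fall/ADL evaluation: accuracy, precision, sensitivity,
specificity and the Matthews correlation coefficient.

All five derive from a 2×2 confusion table with fall as the positive
class:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (true-positive rate)
    specificity = TN / (TN + FP)          (true-negative rate)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC summarizes the whole table in [−1, 1] and stays informative under the
heavy class imbalance typical of fall data.  A ratio whose denominator is
zero is reported as 0 and flagged ``undefined`` rather than raising, so
batch evaluation always completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .signal_io import LABEL_ADL, LABEL_FALL


class MetricsError(ValueError):
    """Invalid input to a metric computation."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; fall is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricValue:
    """A metric plus a flag marking a zero-denominator degenerate case."""

    value: float
    undefined: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class MetricsReport:
    accuracy: MetricValue
    precision: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    mcc: MetricValue

    def to_dict(self) -> dict:
        return {
            name: {"value": mv.value, "undefined": mv.undefined}
            for name, mv in self.__dict__.items()
        }

    def formatted(self) -> dict[str, str]:
        """Percentages to two decimals, MCC to four — the tabular style
        used throughout the study's result tables."""
        return {
            "accuracy": f"{100 * self.accuracy.value:.2f}",
            "precision": f"{100 * self.precision.value:.2f}",
            "sensitivity": f"{100 * self.sensitivity.value:.2f}",
            "specificity": f"{100 * self.specificity.value:.2f}",
            "mcc": f"{self.mcc.value:.4f}",
        }


def confusion_counts(truth: Sequence[str],
                     predicted: Sequence[str]) -> ConfusionCounts:
    """Tally a 2×2 confusion table from parallel label sequences."""
    if len(truth) != len(predicted):
        raise MetricsError(
            f"length mismatch: {len(truth)} truths vs {len(predicted)} predictions")
    if len(truth) == 0:
        raise MetricsError("cannot tally an empty label sequence")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t not in (LABEL_FALL, LABEL_ADL) or p not in (LABEL_FALL, LABEL_ADL):
            raise MetricsError(f"unknown label in pair ({t!r}, {p!r})")
        if t == LABEL_FALL:
            if p == LABEL_FALL:
                tp += 1
            else:
                fn += 1
        else:
            if p == LABEL_FALL:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> MetricValue:
    if den == 0:
        return MetricValue(0.0, undefined=True)
    return MetricValue(num / den)


def accuracy(c: ConfusionCounts) -> MetricValue:
    if c.total == 0:
        raise MetricsError("accuracy of an empty confusion table")
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> MetricValue:
    return _ratio(c.tp, c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> MetricValue:
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> MetricValue:
    return _ratio(c.tn, c.tn + c.fp)


def mcc(c: ConfusionCounts) -> MetricValue:
    """Matthews correlation coefficient; 0 (flagged) if any marginal is
    empty."""
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if 0 in factors:
        return MetricValue(0.0, undefined=True)
    num = c.tp * c.tn - c.fp * c.fn
    return MetricValue(num / math.sqrt(math.prod(factors)))


def evaluate(truth: Sequence[str], predicted: Sequence[str]) -> MetricsReport:
    """All five metrics from parallel truth/prediction label sequences."""
    return report(confusion_counts(truth, predicted))


def report(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        accuracy=accuracy(c),
        precision=precision(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        mcc=mcc(c),
    )
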