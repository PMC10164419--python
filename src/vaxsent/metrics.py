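"""Binary-classification evaluation: confusion counts and derived metrics.

precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R) and
accuracy = (TP+TN)/total.  A ratio with zero denominator is reported as 0
and the metric's name is carried in ``undefined`` so callers can tell a
true zero from an undefined one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["ConfusionCounts", "MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(
        cls, predicted: Iterable[int], actual: Iterable[int]
    ) -> "ConfusionCounts":
        """Tally counts from parallel 0/1 prediction and truth sequences."""
        predicted = list(predicted)
        actual = list(actual)
        if len(predicted) != len(actual):
            raise ValueError("predicted and actual differ in length")
        tp = sum(1 for p, a in zip(predicted, actual) if p == 1 and a == 1)
        fp = sum(1 for p, a in zip(predicted, actual) if p == 1 and a == 0)
        fn = sum(1 for p, a in zip(predicted, actual) if p == 0 and a == 1)
        tn = sum(1 for p, a in zip(predicted, actual) if p == 0 and a == 0)
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "undefined": sorted(self.undefined),
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F-measure from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero items")
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall == 0:
        undefined.add("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    accuracy = (counts.tp + counts.tn) / counts.total
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        undefined=frozenset(undefined),
    )
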