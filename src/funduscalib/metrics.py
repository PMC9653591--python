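"""Validation statistics: confusion-matrix metrics and diameter stability."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "SegmentationMetrics",
    "confusion_metrics",
    "diameter_stats",
    "lesion_area",
]


@dataclass
class ConfusionMatrix:
    """Pixel-level segmentation counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("confusion matrix must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class SegmentationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    iou: float

    def rounded(self, ndigits: int = 3) -> "SegmentationMetrics":
        return SegmentationMetrics(
            *(round(v, ndigits) for v in (self.accuracy, self.sensitivity, self.specificity, self.iou))
        )


def confusion_metrics(cm: ConfusionMatrix) -> SegmentationMetrics:
    """Accuracy, sensitivity, specificity and IoU from pixel counts.

    ``Acc = (tp+tn)/total``, ``Sens = tp/(tp+fn)``, ``Spec = tn/(tn+fp)``,
    ``IoU = tp/(tp+fn+fp)``.  A zero denominator raises for that metric.
    """
    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            raise ZeroDivisionError(f"{name} undefined: zero denominator")
        return num / den

    return SegmentationMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        iou=_ratio(cm.tp, cm.tp + cm.fn + cm.fp, "IoU"),
    )


def diameter_stats(xs: Sequence[float]) -> tuple[float, float, float]:
    """Mean, population standard deviation and coefficient of variation.

    The coefficient of variation ``V = sigma / E`` is dimensionless, so the
    stability of diameter measurements can be compared across cameras with
    different resolutions.
    """
    arr = np.asarray(list(xs), dtype=np.float64)
    if arr.size < 1:
        raise ValueError("need at least one measurement")
    e = float(arr.mean())
    sigma = float(arr.std(ddof=0))
    if e == 0:
        raise ZeroDivisionError("coefficient of variation undefined: zero mean")
    return e, sigma, sigma / e


def lesion_area(px_count: float, pitch_um: float) -> float:
    """Physical lesion area in mm^2 from a pixel count and a pixel pitch (um)."""
    if px_count < 0:
        raise ValueError("pixel count must be >= 0")
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    return px_count * (pitch_um / 1000.0) ** 2
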