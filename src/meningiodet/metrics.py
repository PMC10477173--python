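"""Confusion counts and evaluation metrics.

The counts follow the A/B/C/D naming used throughout this method: A true
negatives, B false positives, C false negatives, D true positives (pixel
level for segmentation, image level for classification).

Two reporting conventions are provided side by side. ``standard`` uses the
textbook definitions (specificity A/(A+B), accuracy (A+D)/total, precision
D/(B+D), FPR B/(A+B)). ``paper_literal`` evaluates the printed formulas of
the source method exactly as published, which disagree with the symbol
glossary (specificity B/(A+B), accuracy (B+D)/total, precision A/(A+C), and
a TPR/FPR pair both printed as A/(A+D)); it exists so the divergence is
auditable, not because those formulas are recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .image_io import ValidationError
from .segmentation import SegmentationMask

CONVENTIONS = ("standard", "paper_literal")


@dataclass(frozen=True)
class ConfusionCounts:
    A: int  # true negatives
    B: int  # false positives
    C: int  # false negatives
    D: int  # true positives

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.A + self.B + self.C + self.D == 0:
            raise ValidationError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale rates plus Dice in [0, 1]; undefined values are None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    seg_accuracy: Optional[float]
    precision: Optional[float]
    tpr: Optional[float]
    fpr: Optional[float]
    dice: Optional[float]
    convention: str = "standard"
    undefined: tuple = field(default_factory=tuple)

    METRIC_NAMES = ("sensitivity", "specificity", "seg_accuracy", "precision", "tpr", "fpr", "dice")

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.METRIC_NAMES}
        d["convention"] = self.convention
        return d


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Pixel-wise confusion counts between two aligned binary masks."""
    p = pred.mask if isinstance(pred, SegmentationMask) else np.asarray(pred, dtype=bool)
    t = truth.mask if isinstance(truth, SegmentationMask) else np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {t.shape}")
    D = int((p & t).sum())
    A = int((~p & ~t).sum())
    B = int((p & ~t).sum())
    C = int((~p & t).sum())
    return ConfusionCounts(A=A, B=B, C=C, D=D)


def _ratio(num: int, den: int, scale: float = 100.0) -> Optional[float]:
    if den == 0:
        return None
    return scale * num / den


def compute_metrics(counts: ConfusionCounts, convention: str = "standard") -> MetricsReport:
    """Evaluate the metric formulas under the chosen convention.

    Metrics with a zero denominator are reported as None and listed in
    ``undefined``; they are never silently imputed as 0.
    """
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    A, B, C, D = counts.A, counts.B, counts.C, counts.D
    sensitivity = _ratio(D, C + D)
    if convention == "standard":
        specificity = _ratio(A, A + B)
        seg_accuracy = _ratio(A + D, counts.total)
        precision = _ratio(D, B + D)
        tpr = sensitivity
        fpr = _ratio(B, A + B)
    else:
        specificity = _ratio(B, A + B)
        seg_accuracy = _ratio(B + D, counts.total)
        precision = _ratio(A, A + C)
        tpr = _ratio(A, A + D)
        fpr = _ratio(A, A + D)
    dice = _ratio(2 * D, 2 * D + B + C, scale=1.0)
    report = MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        seg_accuracy=seg_accuracy,
        precision=precision,
        tpr=tpr,
        fpr=fpr,
        dice=dice,
        convention=convention,
    )
    undefined = tuple(n for n in MetricsReport.METRIC_NAMES if getattr(report, n) is None)
    return MetricsReport(**{**report.as_dict(), "undefined": undefined}) if undefined else report


def aggregate_reports(reports) -> MetricsReport:
    """Unweighted arithmetic mean per metric over per-image reports."""
    reports = list(reports)
    if not reports:
        raise ValidationError("cannot aggregate an empty report list")
    conventions = {r.convention for r in reports}
    if len(conventions) > 1:
        raise ValidationError(f"mixed conventions: {conventions}")
    means = {}
    undefined = []
    for name in MetricsReport.METRIC_NAMES:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            means[name] = float(np.mean(vals))
        else:
            means[name] = None
            undefined.append(name)
    return MetricsReport(
        convention=conventions.pop(), undefined=tuple(undefined), **means
    )
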