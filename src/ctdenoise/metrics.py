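"""Objective image-quality metrics and diagnostic-accuracy summaries.

Quality of a denoised image against its clean reference is scored with the
standard trio

    MSE  = (1/AB) sum (z_ij - z'_ij)^2
    RMSE = sqrt(MSE)
    PSNR = 10 log10(L^2 / MSE)   [dB]

where L is the gray range of the reference.  PSNR is +inf when the images
are identical.  Diagnostic performance on diseased / non-diseased groups is
summarized as sensitivity, specificity and accuracy percentages from a 2x2
confusion table, reported to one decimal, rounded half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError, UndefinedMetricError
from .image_io import Image

__all__ = [
    "QualityReport",
    "ConfusionTable",
    "SubjectiveGrade",
    "SUBJECTIVE_LABELS",
    "mse",
    "rmse",
    "psnr",
    "quality_report",
    "diagnostic_summary",
]


def _pixels(x) -> np.ndarray:
    return np.asarray(getattr(x, "pixels", x), dtype=np.float64)


def _check_shapes(ref, test) -> tuple[np.ndarray, np.ndarray]:
    a, b = _pixels(ref), _pixels(test)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


@dataclass(frozen=True)
class QualityReport:
    """PSNR/RMSE/MSE bundle for one (reference, test) pair."""

    psnr: float
    rmse: float
    mse: float
    gray_range: float

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr,
            "rmse": self.rmse,
            "mse": self.mse,
            "gray_range": self.gray_range,
        }


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 diagnostic counts: diseased (tp + fn) and non-diseased (tn + fp)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")


#: Subjective image-quality rubric: level -> label.
SUBJECTIVE_LABELS = {1: "Poor", 2: "General", 3: "Good", 4: "Excellent"}


@dataclass(frozen=True)
class SubjectiveGrade:
    """A 4-level subjective image grade; level and label must correspond."""

    level: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.level not in SUBJECTIVE_LABELS:
            raise ParameterError(f"level must be 1..4, got {self.level}")
        expected = SUBJECTIVE_LABELS[self.level]
        if self.label == "":
            object.__setattr__(self, "label", expected)
        elif self.label != expected:
            raise ParameterError(f"level {self.level} must be labelled {expected!r}, got {self.label!r}")


def mse(ref, test) -> float:
    """Mean squared gray-level difference over the full image."""
    a, b = _check_shapes(ref, test)
    return float(np.mean((a - b) ** 2))


def rmse(ref, test) -> float:
    """Root mean squared gray-level difference."""
    return math.sqrt(mse(ref, test))


def psnr(ref, test, L: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``math.inf`` when images match.

    ``L`` defaults to the gray range of ``ref`` when it is an :class:`Image`.
    """
    if L is None:
        L = getattr(ref, "gray_range", None)
        if L is None:
            raise ParameterError("L is required when ref carries no gray_range")
    if not L > 0:
        raise ParameterError(f"L must be > 0, got {L}")
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(L * L / err)


def quality_report(ref, test, L: float | None = None) -> QualityReport:
    """Score ``test`` against ``ref`` and return the full metric bundle."""
    if L is None:
        L = getattr(ref, "gray_range", 255.0)
    err = mse(ref, test)
    return QualityReport(
        psnr=math.inf if err == 0.0 else 10.0 * math.log10(L * L / err),
        rmse=math.sqrt(err),
        mse=err,
        gray_range=float(L),
    )


def _round_half_away(value: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def diagnostic_summary(ct: ConfusionTable) -> dict[str, float]:
    """Sensitivity, specificity and accuracy as percentages (1 decimal).

    sensitivity = 100 tp/(tp+fn), specificity = 100 tn/(tn+fp),
    accuracy = 100 (tp+tn)/total; all rounded half-away-from-zero.
    """
    if ct.tp + ct.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no diseased cases (tp + fn = 0)")
    if ct.tn + ct.fp == 0:
        raise UndefinedMetricError("specificity undefined: no non-diseased cases (tn + fp = 0)")
    total = ct.tp + ct.fn + ct.tn + ct.fp
    return {
        "sensitivity": _round_half_away(100.0 * ct.tp / (ct.tp + ct.fn)),
        "specificity": _round_half_away(100.0 * ct.tn / (ct.tn + ct.fp)),
        "accuracy": _round_half_away(100.0 * (ct.tp + ct.tn) / total),
    }
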