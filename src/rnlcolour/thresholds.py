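"""Discrimination thresholds as a function of background contrast.

Behavioural discrimination thresholds rise with the colour contrast between
the adapting background and the stimuli viewed on it.  Over modest to strong
background contrasts the relationship is well described by a straight line,

    threshold(JND) = intercept + slope · background_contrast(JND),

fitted here by ordinary least squares with Pearson correlation diagnostics.
Below the line's crossing of the 1-JND floor, thresholds are clamped at
1 JND — the receptor-noise model's theoretical limit — rather than modelled:
the "dipper" regime (detection thresholds at zero background contrast exceed
the best discrimination thresholds at small pedestal contrasts) is reported
descriptively by :func:`dipper_summary`, not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .contrast import stimulus_contrast
from .receptors import VisualSystem
from .spectra import Spectrum

__all__ = [
    "ThresholdPoint",
    "ThresholdModel",
    "stimulus_background_contrast",
    "fit_threshold_line",
    "predict_threshold",
    "dipper_summary",
]

#: Theoretical discrimination floor of the receptor-noise model, in JND.
RNL_FLOOR_JND = 1.0


@dataclass(frozen=True)
class ThresholdPoint:
    """One (background contrast, threshold) observation for one subject."""
    background_contrast: float  # JND, rewarded stimulus vs background
    threshold: float            # JND
    subject: str = ""
    task: str = "discrimination"  # or "detection"

    def __post_init__(self) -> None:
        if self.background_contrast < 0 or self.threshold < 0:
            raise ValueError("contrast and threshold must be non-negative")
        if self.task not in ("discrimination", "detection"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass(frozen=True)
class ThresholdModel:
    """Linear threshold-vs-background-contrast model with diagnostics."""
    slope: float
    intercept: float
    r_squared: float
    pearson_p: float
    n_points: int

    @property
    def one_jnd_crossing(self) -> float:
        """Background contrast where the line predicts exactly 1 JND."""
        if self.slope == 0:
            raise ZeroDivisionError("flat line never crosses 1 JND")
        return (RNL_FLOOR_JND - self.intercept) / self.slope


def stimulus_background_contrast(stim: Spectrum, background: Spectrum,
                                 vs: VisualSystem) -> float:
    """ΔS (JND) between a stimulus and the background it appears on,
    with receptors adapted to that background."""
    return stimulus_contrast(vs, stim, background, background)


def fit_threshold_line(points: Sequence[ThresholdPoint]) -> ThresholdModel:
    """Ordinary least squares on discrimination points only.

    Detection points (zero background contrast by convention) belong to
    the dipper regime and are excluded.  Requires ≥3 points with variance
    in background contrast.  The p-value is the two-sided Pearson
    correlation test via the exact t transform.
    """
    disc = [p for p in points if p.task == "discrimination"]
    if len(disc) < 3:
        raise ValueError("need at least three discrimination points")
    x = np.array([p.background_contrast for p in disc])
    y = np.array([p.threshold for p in disc])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in background contrast")
    res = stats.linregress(x, y)
    return ThresholdModel(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2),
                          pearson_p=float(res.pvalue),
                          n_points=len(disc))


def predict_threshold(model: ThresholdModel,
                      background_contrast: float) -> float:
    """Background-corrected discrimination threshold, floored at 1 JND."""
    if background_contrast < 0:
        raise ValueError("background contrast must be non-negative")
    raw = model.intercept + model.slope * background_contrast
    return max(RNL_FLOOR_JND, raw)


def dipper_summary(points: Sequence[ThresholdPoint]) -> dict:
    """Detection vs discrimination comparison (the dipper function).

    Reports the mean detection threshold, the minimum discrimination
    threshold, their ratio, and whether a dip is present (minimum
    discrimination strictly below detection).
    """
    det = [p.threshold for p in points if p.task == "detection"]
    disc = [p.threshold for p in points if p.task == "discrimination"]
    if not det:
        raise ValueError("no detection points")
    if len(disc) < 2:
        raise ValueError("need at least two discrimination points")
    detection = float(np.mean(det))
    min_disc = float(min(disc))
    if min_disc <= 0:
        raise ValueError("non-positive discrimination threshold")
    return {
        "detection_threshold": detection,
        "min_discrimination_threshold": min_disc,
        "ratio": detection / min_disc,
        "dip_present": bool(min_disc < detection),
        "n_detection": len(det),
        "n_discrimination": len(disc),
    }
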