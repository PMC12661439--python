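"""Detector and observation-volume calibration.

Dead time and afterpulsing are calibrated from constant-intensity traces of a
concentrated dye: with molecular fluctuations absent, Mandel's Q obeys
Q = 2 p_a - 2 I tau_d, so a straight line over several laser powers yields
both detector parameters.  The observation volume follows from a PCH fit of a
dye solution of known concentration via V = N / (C * N_A).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import AVOGADRO
from .pch import PCHFit

__all__ = [
    "DeadTimeCalibration",
    "VolumeCalibration",
    "LabelingCalibration",
    "fit_dead_time",
    "calibrate_volume",
    "labeling_efficiency_from_timecourse",
]


@dataclass
class DeadTimeCalibration:
    """Result of the linear Q-vs-intensity detector calibration."""

    afterpulse_probability: float
    dead_time: float
    fit_points: list[tuple[float, float]]
    r_squared: float
    residuals: np.ndarray


@dataclass
class VolumeCalibration:
    """Observation volume from a known-concentration dye measurement."""

    observation_volume: float  # liters
    fitted_number: float
    known_concentration: float  # molar

    @property
    def volume_fl(self) -> float:
        return self.observation_volume * 1e15


@dataclass
class LabelingCalibration:
    """Saturating-exponential fit of a staining time course."""

    equilibrium_time: float  # hours; NaN when the plateau is unbounded
    rate: float  # 1/h
    plateau: float
    normalized_curve: pd.DataFrame
    saturated: bool


def fit_dead_time(points) -> DeadTimeCalibration:
    """Fit (intensity, Q) pairs to the line Q = 2 p_a - 2 I tau_d.

    Requires at least three points spanning a >= 2x intensity range.  The
    slope gives tau_d = -slope/2 and the intercept p_a = intercept/2; a
    negative fitted dead time is clipped to 0 with a warning, a negative
    afterpulse probability likewise.
    """
    pts = [(float(i), float(q)) for i, q in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 (intensity, Q) points")
    intensity = np.array([p[0] for p in pts])
    q = np.array([p[1] for p in pts])
    if intensity.min() <= 0 or intensity.max() / intensity.min() < 2.0 - 1e-9:
        raise ValueError("intensities must be positive and span a >= 2x range")
    if np.unique(intensity).size < 2:
        raise ValueError("degenerate design: all intensities equal")

    slope, intercept = np.polyfit(intensity, q, 1)
    fitted = slope * intensity + intercept
    residuals = q - fitted
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else math.nan

    dead_time = -slope / 2.0
    if dead_time < 0:
        warnings.warn("fitted dead time is negative; reporting 0", stacklevel=2)
        dead_time = 0.0
    p_a = intercept / 2.0
    if p_a < 0:
        warnings.warn(
            "fitted afterpulse probability is negative; reporting 0", stacklevel=2
        )
        p_a = 0.0
    return DeadTimeCalibration(
        afterpulse_probability=p_a,
        dead_time=dead_time,
        fit_points=pts,
        r_squared=r2,
        residuals=residuals,
    )


def calibrate_volume(fit: PCHFit, known_concentration: float) -> VolumeCalibration:
    """Observation volume V = N / (C * N_A) from a single-dye PCH fit."""
    if known_concentration <= 0:
        raise ValueError("known concentration must be positive")
    if not fit.converged or fit.number <= 0:
        raise ValueError("volume calibration requires a successful PCH fit")
    volume = fit.number / (known_concentration * AVOGADRO)
    v_fl = volume * 1e15
    if not 0.1 <= v_fl <= 10.0:
        warnings.warn(
            f"calibrated volume {v_fl:.3g} fL is outside the plausible "
            "0.1-10 fL confocal range",
            stacklevel=2,
        )
    return VolumeCalibration(
        observation_volume=volume,
        fitted_number=fit.number,
        known_concentration=known_concentration,
    )


#: Fraction of the fitted plateau that defines "labeling has equilibrated".
EQUILIBRIUM_PLATEAU_FRACTION = 0.95


def labeling_efficiency_from_timecourse(table: pd.DataFrame) -> LabelingCalibration:
    """Characterize a staining time course (stain_time_h, ratio).

    Fits ratio(t) = plateau * (1 - exp(-rate t)), max-normalizes the curve,
    and reports the equilibrium time: the earliest time at which the fitted
    curve reaches 95 % of its plateau, t95 = ln(20)/rate.  A constant series
    equilibrates at the first time point.  Non-saturating data (plateau
    uncertainty unbounded) are flagged with ``saturated=False`` and an
    undefined equilibrium time.
    """
    t = np.asarray(table.iloc[:, 0], dtype=float)
    ratio = np.asarray(table.iloc[:, 1], dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(ratio < 0):
        raise ValueError("ratios must be >= 0")

    normalized = pd.DataFrame(
        {"stain_time_h": t, "ratio": ratio / ratio.max() if ratio.max() > 0 else ratio}
    )
    if np.allclose(ratio, ratio[0]):
        return LabelingCalibration(
            equilibrium_time=float(t[0]),
            rate=math.inf,
            plateau=float(ratio[0]),
            normalized_curve=normalized,
            saturated=True,
        )

    def model(tt, plateau, rate):
        return plateau * (1.0 - np.exp(-rate * tt))

    try:
        popt, pcov = curve_fit(
            model,
            t,
            ratio,
            p0=(float(ratio.max()), 1.0 / max(t[0], 1e-6)),
            bounds=((0.0, 1e-9), (np.inf, np.inf)),
            maxfev=10_000,
        )
    except RuntimeError:
        return LabelingCalibration(math.nan, math.nan, math.nan, normalized, False)
    plateau, rate = (float(v) for v in popt)
    plateau_sd = math.sqrt(abs(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    saturated = plateau_sd < plateau  # plateau resolved within its own size
    t95 = math.log(1.0 / (1.0 - EQUILIBRIUM_PLATEAU_FRACTION)) / rate
    return LabelingCalibration(
        equilibrium_time=t95 if saturated else math.nan,
        rate=rate,
        plateau=plateau,
        normalized_curve=normalized,
        saturated=saturated,
    )
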