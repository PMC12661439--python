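"""Exponential kinetics: oligomer dissociation and photobleaching fits.

Dissociation after light-off is modeled as a single-exponential relaxation of
the relative brightness, B(t) = A exp(-t/tau) + C, with half-life
tau_1/2 = ln2 * tau.  Photobleaching trajectories are fit to I(t) = exp(-k t)
after frame-window trimming and normalization; rate constants are compared
across fluorophores via the extinction-weighted excitation power
E_C = P_lambda * eps_lambda.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "BleachFit",
    "fit_exponential_decay",
    "fit_photobleach",
    "prepare_bleach_frames",
    "relative_excitation_power",
    "underestimation_bound",
]


@dataclass
class DecayFit:
    """Single-exponential decay fit B(t) = A exp(-t/tau) + C (t in minutes)."""

    amplitude: float
    baseline: float
    lifetime: float
    r_squared: float
    success: bool
    message: str = ""
    covariance: np.ndarray | None = None

    @property
    def half_life(self) -> float:
        """tau_1/2 = ln2 * tau, minutes."""
        return math.log(2.0) * self.lifetime


@dataclass
class BleachFit:
    """Photobleaching fit I(t) = exp(-k t) (t in seconds)."""

    rate_constant: float
    r_squared: float
    success: bool
    message: str = ""


def _r_squared(values: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - ss_res / ss_tot


def fit_exponential_decay(times, values) -> DecayFit:
    """Fit a relative-brightness decay to A exp(-t/tau) + C.

    Nonlinear least squares with initial guesses A = B(0) - B(end),
    C = B(end), tau = range(t)/3 and bounds A in [0, 10], C in [0, 5],
    tau in (0, 10 * range(t)].  Degenerate inputs (constant series, amplitude
    collapsing to zero, or parameters pinned at bounds) are returned with
    ``success=False`` rather than raising.
    """
    t = np.asarray(times, dtype=float)
    b = np.asarray(values, dtype=float)
    if t.size != b.size:
        raise ValueError("times and values must have the same length")
    if t.size < 4:
        raise ValueError("need at least 4 points for a three-parameter fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    t_range = float(t[-1] - t[0])
    a0 = float(np.clip(b[0] - b[-1], 1e-6, 10.0))
    c0 = float(np.clip(b[-1], 0.0, 5.0))
    tau0 = t_range / 3.0
    lower = (0.0, 0.0, 1e-9 * t_range)
    upper = (10.0, 5.0, 10.0 * t_range)

    def model(tt, a, c, tau):
        return a * np.exp(-tt / tau) + c

    try:
        popt, pcov = curve_fit(
            model, t, b, p0=(a0, c0, tau0), bounds=(lower, upper), maxfev=10_000
        )
    except RuntimeError as err:
        return DecayFit(a0, c0, tau0, math.nan, False, f"no convergence: {err}")

    a, c, tau = (float(v) for v in popt)
    r2 = _r_squared(b, model(t, *popt))
    flagged = []
    if a < 1e-6 or math.isnan(r2):
        flagged.append("amplitude is degenerate; lifetime unidentifiable")
    if tau >= upper[2] * (1 - 1e-6) or tau <= lower[2] * (1 + 1e-6):
        flagged.append("lifetime pinned at bound")
    return DecayFit(
        amplitude=a,
        baseline=c,
        lifetime=tau,
        r_squared=r2,
        success=not flagged,
        message="; ".join(flagged),
        covariance=pcov,
    )


def prepare_bleach_frames(
    frame_intensities,
    frame_interval: float,
    first_keep: int = 3,
    last_keep: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Trim a frame series to [first_keep, last_keep] and normalize.

    Frames are numbered from 1; the first retained frame defines t = 0 and
    intensity 1.  Returns (times_s, normalized_intensity).
    """
    i = np.asarray(frame_intensities, dtype=float)
    if not 1 <= first_keep <= last_keep <= i.size:
        raise ValueError("frame window outside the recorded series")
    window = i[first_keep - 1 : last_keep]
    times = np.arange(window.size) * frame_interval
    return times, window / window[0]


def fit_photobleach(times, normalized_intensity) -> BleachFit:
    """Fit a normalized bleaching trajectory to I(t) = exp(-k t), k >= 0.

    An increasing trace (best k < 0) is reported as k = 0 with a warning.
    """
    t = np.asarray(times, dtype=float)
    i = np.asarray(normalized_intensity, dtype=float)
    if t.size != i.size or t.size < 2:
        raise ValueError("need matching time/intensity arrays of length >= 2")

    def model(tt, k):
        return np.exp(-k * tt)

    # unconstrained fit first, to detect a rising trace honestly
    try:
        popt, _ = curve_fit(model, t, i, p0=(0.1 / max(t[-1], 1e-12),), maxfev=10_000)
    except RuntimeError as err:
        return BleachFit(math.nan, math.nan, False, f"no convergence: {err}")
    k = float(popt[0])
    if k < 0:
        warnings.warn(
            "intensity increases over the trace; clipping bleach rate to 0",
            stacklevel=2,
        )
        k = 0.0
    return BleachFit(k, _r_squared(i, model(t, k)), True)


def relative_excitation_power(incident_power: float, extinction_coefficient: float) -> float:
    """E_C = P_lambda * eps_lambda: extinction-weighted excitation power.

    Units are the product of the inputs (e.g. uW * M^-1 cm^-1), reported
    as-is; the quantity only serves to compare photobleaching of fluorophores
    excited at different wavelengths.
    """
    if incident_power < 0 or extinction_coefficient < 0:
        raise ValueError("power and extinction coefficient must be >= 0")
    return incident_power * extinction_coefficient


def underestimation_bound(acquisition_time: float, half_life: float) -> float:
    """Fraction of oligomer lost during a post-illumination acquisition.

    1 - exp(-ln2 * t_acq / tau_half) with the acquisition time in seconds and
    the dissociation half-life in minutes: the systematic underestimate of
    the oligomerization state caused by dark-state reversion during the
    measurement itself.
    """
    if acquisition_time <= 0 or half_life <= 0:
        raise ValueError("acquisition time and half-life must be positive")
    return 1.0 - math.exp(-math.log(2.0) * (acquisition_time / 60.0) / half_life)
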