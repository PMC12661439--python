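"""Synthetic photon-stream and kinetics data with known ground truth.

Monte-Carlo emulation of single-point FFS acquisitions: Poisson photon
emission from diffusing particles in a 3D-Gaussian observation profile,
monomer/dimer/tetramer label statistics with per-label fluorescence
probability, detector dead time and afterpulsing, slow intensity drift, and
the exponential time series used for dissociation and photobleaching
analysis.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .brightness import apparent_relative_brightness
from .geometry import AVOGADRO, DEFAULT_PSF, PSFGeometry
from .trace import PhotonCountTrace

__all__ = [
    "Species",
    "SimulationConfig",
    "BoxSizingError",
    "DetectorSaturationError",
    "simulate_snapshot_counts",
    "simulate_diffusion_trace",
    "apply_detector",
    "simulate_spot",
    "simulate_dissociation_series",
    "simulate_bleach_trace",
    "simulate_labeling_timecourse",
    "box_count_for_concentration",
    "reference_count_for_concentration",
]

#: Particles are simulated individually only where B >= this threshold; the
#: remainder of the box enters as a Poisson background with the exact
#: analytic mean.  See docs/methods.md for the (negligible) variance bias.
CORE_PROFILE_THRESHOLD = 1e-3

#: Maximum tolerated fraction of the profile integral lost outside the box.
MAX_PROFILE_TRUNCATION = 1e-3


class BoxSizingError(ValueError):
    """Simulation box too small relative to the detection profile."""


class DetectorSaturationError(RuntimeError):
    """A bin's true counts would saturate the first-order dead-time model."""


@dataclass(frozen=True)
class Species:
    """A simulated oligomeric species.

    ``brightness`` is the per-label focal count rate (cpsm); an ``subunits``-mer
    carries that many labels, each independently fluorescent with probability
    ``fluorescent_probability``.  ``mean_count`` is the mean number of
    particles (oligomers, not labels) in the simulation box.
    """

    brightness: float
    mean_count: float
    fluorescent_probability: float = 1.0
    subunits: int = 1

    def __post_init__(self) -> None:
        if self.brightness < 0 or self.mean_count < 0:
            raise ValueError("brightness and mean_count must be >= 0")
        if not 0.0 <= self.fluorescent_probability <= 1.0:
            raise ValueError("fluorescent_probability must lie in [0, 1]")
        if self.subunits < 1:
            raise ValueError("subunits must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated single-point FFS acquisition.

    Defaults mirror a typical live-cell measurement: 20 kHz binning, 30 s
    acquisition, 15 ns detector dead time, and the 1.02 fL default observation
    geometry.  The diffusion coefficient default (25 um^2/s) is a typical
    value for a small cytoplasmic protein; the one-bin count statistics are
    independent of it.
    """

    seed: int = 0
    duration: float = 30.0
    sampling_frequency: float = 20_000.0
    geometry: PSFGeometry = DEFAULT_PSF
    box_lengths: tuple[float, float, float] | None = None
    diffusion_coefficient: float = 25.0
    species: tuple[Species, ...] = (Species(brightness=20_000.0, mean_count=500.0),)
    dead_time: float = 15e-9
    afterpulse_probability: float = 0.0
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_frequency <= 0:
            raise ValueError("duration and sampling_frequency must be positive")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.dead_time < 0 or self.dead_time * self.sampling_frequency >= 1:
            raise ValueError("need 0 <= dead_time * sampling_frequency < 1")
        if not 0.0 <= self.afterpulse_probability <= 1.0:
            raise ValueError("afterpulse_probability must lie in [0, 1]")
        if self.box_lengths is None:
            g = self.geometry
            object.__setattr__(
                self,
                "box_lengths",
                (8.0 * g.beam_waist, 8.0 * g.beam_waist, 8.0 * g.axial_waist),
            )
        lx, ly, lz = self.box_lengths
        g = self.geometry
        if lx < 8 * g.beam_waist or ly < 8 * g.beam_waist or lz < 8 * g.axial_waist:
            raise BoxSizingError(
                "box must span at least 8 beam waists laterally and 8 axial "
                "waists axially"
            )
        truncated = 1.0 - g.profile_box_integral(
            (lx / 2, ly / 2, lz / 2)
        ) / g.psf_volume
        if truncated > MAX_PROFILE_TRUNCATION:
            raise BoxSizingError(
                f"box truncates {truncated:.1e} of the detection profile"
            )
        if not isinstance(self.species, tuple):
            object.__setattr__(self, "species", tuple(self.species))

    @property
    def box_volume(self) -> float:
        lx, ly, lz = self.box_lengths
        return lx * ly * lz

    @property
    def n_bins(self) -> int:
        return int(round(self.duration * self.sampling_frequency))

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def box_count_for_concentration(
    concentration_nm: float, config: SimulationConfig
) -> float:
    """Mean particles in the simulation box at a molar concentration (nM)."""
    per_um3 = concentration_nm * 1e-9 * AVOGADRO * 1e-15  # molecules per fL
    return per_um3 * config.box_volume


def reference_count_for_concentration(
    concentration_nm: float, geometry: PSFGeometry = DEFAULT_PSF
) -> float:
    """Mean particles in the fitting reference volume at a concentration (nM)."""
    return concentration_nm * 1e-9 * AVOGADRO * geometry.reference_volume * 1e-15


def _core_half_lengths(config: SimulationConfig) -> tuple[float, float, float]:
    g = config.geometry
    r = math.sqrt(math.log(1.0 / CORE_PROFILE_THRESHOLD) / 2.0)
    lx, ly, lz = config.box_lengths
    return (
        min(r * g.beam_waist, lx / 2),
        min(r * g.beam_waist, ly / 2),
        min(r * g.axial_waist, lz / 2),
    )


def _label_classes(sp: Species) -> list[tuple[float, float]]:
    """Expand a species into (lit-label count, mean particle count) classes.

    A Poisson population of n-mers whose labels light independently with
    probability p_f is exactly a superposition of independent Poisson
    populations with fixed lit-label count l = 1..n and means
    mean_count * Binomial(n, p_f).pmf(l); the l = 0 class is invisible.
    """
    if sp.subunits == 1 and sp.fluorescent_probability == 1.0:
        return [(1.0, sp.mean_count)]
    from scipy.stats import binom

    return [
        (float(l), sp.mean_count * float(binom.pmf(l, sp.subunits, sp.fluorescent_probability)))
        for l in range(1, sp.subunits + 1)
    ]


def simulate_snapshot_counts(
    config: SimulationConfig, n_bins: int
) -> PhotonCountTrace:
    """Independent-snapshot Monte-Carlo photon counts (ideal detector).

    Each bin is an independent realization: the particle count of each species
    is Poisson with the configured box mean, positions are uniform in the box,
    and the bin's photon count is Poisson with mean
    sum_particles labels_i * (eps/f_s) * B(r_i).  This is the brute-force
    oracle for the semi-analytic PCH model.  Particles are simulated
    explicitly inside the region where B >= 1e-3; the rest of the box enters
    as a Poisson term with the exact analytic mean intensity.

    Detector artifacts are *not* applied; see :func:`apply_detector` /
    :func:`simulate_spot`.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(config.seed)
    g = config.geometry
    core = _core_half_lengths(config)
    box_half = tuple(l / 2 for l in config.box_lengths)
    core_volume = 8.0 * core[0] * core[1] * core[2]
    b_core = g.profile_box_integral(core)
    b_box = g.profile_box_integral(box_half)

    lam = np.zeros(n_bins)
    scale = np.array([2 * c for c in core])
    offset = np.array(core)
    for sp in config.species:
        if sp.brightness == 0.0 or sp.mean_count == 0.0:
            continue
        eps_bin = sp.brightness / config.sampling_frequency
        for lit, mean_count in _label_classes(sp):
            if mean_count == 0.0:
                continue
            density = mean_count / config.box_volume
            mean_core = density * core_volume
            # far field: exact mean intensity of particles outside the core
            lam += lit * eps_bin * density * (b_box - b_core)
            chunk = max(1, int(2e7 / max(mean_core, 1.0)))
            for start in range(0, n_bins, chunk):
                m = min(chunk, n_bins - start)
                counts = rng.poisson(mean_core, size=m)
                total = int(counts.sum())
                if total == 0:
                    continue
                pos = rng.random((total, 3)) * scale - offset
                weights = (lit * eps_bin) * g.profile(
                    pos[:, 0], pos[:, 1], pos[:, 2]
                )
                idx = np.repeat(np.arange(m), counts)
                lam[start : start + m] += np.bincount(
                    idx, weights=weights, minlength=m
                )

    counts = rng.poisson(lam)
    return PhotonCountTrace(
        counts,
        config.sampling_frequency,
        {"generator": "snapshot", "seed": config.seed},
    )


def simulate_diffusion_trace(config: SimulationConfig) -> PhotonCountTrace:
    """Brownian-dynamics photon-count trace (ideal detector).

    Euler-Maruyama displacements with per-axis std sqrt(2 D dt) and periodic
    boundaries; the one-bin marginal distribution matches
    :func:`simulate_snapshot_counts` for the same configuration.  A nonzero
    ``drift_slope`` modulates the mean intensity linearly by
    (1 + drift_slope * t / duration), emulating slow cell-movement drift.
    """
    rng = np.random.default_rng(config.seed)
    g = config.geometry
    n_bins = config.n_bins
    dt = 1.0 / config.sampling_frequency
    step_sd = math.sqrt(2.0 * config.diffusion_coefficient * dt)
    if step_sd > g.beam_waist / 2.0:
        warnings.warn(
            "Brownian step exceeds half a beam waist per bin; the profile is "
            "temporally under-sampled",
            stacklevel=2,
        )
    lengths = np.array(config.box_lengths)
    lam = np.zeros(n_bins)
    for sp in config.species:
        if sp.brightness == 0.0:
            continue
        eps_bin = sp.brightness / config.sampling_frequency
        class_sizes = [
            (lit, int(rng.poisson(mean))) for lit, mean in _label_classes(sp)
        ]
        m = sum(size for _, size in class_sizes)
        if m == 0:
            continue
        pos = rng.uniform(-lengths / 2, lengths / 2, size=(m, 3))
        weights = eps_bin * np.repeat(
            [lit for lit, _ in class_sizes], [size for _, size in class_sizes]
        )
        chunk = max(256, int(4e6 / m))
        for start in range(0, n_bins, chunk):
            t_c = min(chunk, n_bins - start)
            steps = rng.normal(0.0, step_sd, size=(t_c, m, 3))
            traj = pos + np.cumsum(steps, axis=0)
            traj = (traj + lengths / 2) % lengths - lengths / 2
            b = g.profile(traj[..., 0], traj[..., 1], traj[..., 2])
            lam[start : start + t_c] += b @ weights
            pos = traj[-1]
    if config.drift_slope != 0.0:
        t = (np.arange(n_bins) + 0.5) / n_bins
        lam *= 1.0 + config.drift_slope * t
    counts = rng.poisson(lam)
    return PhotonCountTrace(
        counts,
        config.sampling_frequency,
        {"generator": "diffusion", "seed": config.seed},
    )


def apply_detector(
    trace: PhotonCountTrace,
    dead_time: float,
    afterpulse_probability: float,
    seed: int,
) -> PhotonCountTrace:
    """Apply first-order dead-time loss and afterpulsing to an ideal trace.

    Each photon in a bin with k true counts is lost with probability
    (k - 1) * tau_d * f_s (binomial thinning, first order in the dead time);
    each surviving photon spawns one afterpulse with probability p_a.  For a
    constant source of intensity I this reproduces the detector calibration
    line Q = 2 p_a - 2 I tau_d to first order.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    if not 0.0 <= afterpulse_probability <= 1.0:
        raise ValueError("afterpulse_probability must lie in [0, 1]")
    if dead_time == 0.0 and afterpulse_probability == 0.0:
        return PhotonCountTrace(
            trace.counts.copy(), trace.sampling_frequency, dict(trace.metadata)
        )
    rng = np.random.default_rng(seed)
    k = trace.counts.astype(np.int64)
    loss_scale = dead_time * trace.sampling_frequency
    if loss_scale > 0 and k.size and float(k.max()) * loss_scale >= 1.0:
        raise DetectorSaturationError(
            "dead time * sampling_frequency * max(counts) >= 1; the "
            "first-order dead-time model saturates"
        )
    p_loss = np.clip((k - 1) * loss_scale, 0.0, 1.0)
    detected = k - rng.binomial(k, p_loss)
    if afterpulse_probability > 0.0:
        detected = detected + rng.binomial(detected, afterpulse_probability)
    meta = dict(trace.metadata)
    meta.update(dead_time=dead_time, afterpulse_probability=afterpulse_probability)
    return PhotonCountTrace(detected, trace.sampling_frequency, meta)


def simulate_spot(config: SimulationConfig, n_bins: int | None = None) -> PhotonCountTrace:
    """Snapshot counts with the configured detector applied: one FFS spot."""
    n = config.n_bins if n_bins is None else n_bins
    ideal = simulate_snapshot_counts(config, n)
    return apply_detector(
        ideal, config.dead_time, config.afterpulse_probability, config.seed + 1
    )


def simulate_dissociation_series(
    x0: float,
    tau: float,
    n_oligomer: int,
    timepoints,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-brightness decay after light-off.

    The oligomer fraction relaxes as x(t) = x0 * exp(-t / tau) (tau in
    minutes) and is pushed through the two-state apparent-brightness model;
    homoscedastic Gaussian noise of ``noise_sd`` is added.

    Returns a table with columns ``time_min`` and ``relative_brightness``.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must lie in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(timepoints, dtype=float)
    x = x0 * np.exp(-t / tau)
    b = np.array([apparent_relative_brightness(xi, n_oligomer) for xi in x])
    if noise_sd > 0:
        b = b + np.random.default_rng(seed).normal(0.0, noise_sd, size=b.size)
    return pd.DataFrame({"time_min": t, "relative_brightness": b})


def simulate_bleach_trace(
    k: float, timepoints, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Normalized photobleaching trajectory I(t) = exp(-k t), t in seconds."""
    if k < 0:
        raise ValueError("bleach rate constant must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    i = np.exp(-k * t)
    if noise_sd > 0:
        i = i + np.random.default_rng(seed).normal(0.0, noise_sd, size=i.size)
    return pd.DataFrame({"time_s": t, "normalized_intensity": i})


#: Default labeling rate constant (1/h): plateau (95 % of equilibrium) is
#: reached by 5 h, consistent with staining reaching equilibrium within 6 h.
DEFAULT_LABELING_RATE = 0.6


def simulate_labeling_timecourse(
    equilibrium_ratio: float = 1.0,
    rate: float = DEFAULT_LABELING_RATE,
    times=(2.0, 4.0, 6.0, 10.0, 24.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Saturating dye:reference intensity-ratio time course, max-normalized.

    ratio(t) = equilibrium_ratio * (1 - exp(-rate * t)), then divided by its
    maximum observed value (as staining calibrations are reported).  Columns:
    ``stain_time_h``, ``ratio``.
    """
    if equilibrium_ratio <= 0 or rate <= 0:
        raise ValueError("equilibrium_ratio and rate must be positive")
    t = np.asarray(times, dtype=float)
    ratio = equilibrium_ratio * (1.0 - np.exp(-rate * t))
    if noise_sd > 0:
        ratio = ratio + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    ratio = ratio / ratio.max()
    return pd.DataFrame({"stain_time_h": t, "ratio": ratio})
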