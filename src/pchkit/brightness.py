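"""From fitted brightness to biology: oligomer fractions and concentrations.

A homo-n-mer whose labels are each fluorescent with probability p_f has an
apparent brightness of (1 + (n-1) p_f) times the monomer: the distribution of
lit labels L ~ Binomial(n, p_f) enters the measurement intensity-weighted, so
the apparent brightness is E[L^2]/E[L] label units.  A two-state
monomer/oligomer mixture with oligomer fraction x has apparent relative
brightness (3x+1)/(x+1) for a dimer and (15x+1)/(3x+1) for a tetramer (ideal
brightness ratios 2 and 4); inverting those relations converts a
labeling-corrected relative brightness into an oligomer fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import AVOGADRO

__all__ = [
    "BrightnessModel",
    "CorrectedBrightness",
    "AggregationResult",
    "fluorescence_probability",
    "correct_relative_brightness",
    "apparent_relative_brightness",
    "oligomer_fraction",
    "apparent_two_state",
    "protomer_concentration",
    "aggregate_cell",
]


@dataclass(frozen=True)
class BrightnessModel:
    """Brightness of an n-mer with per-label fluorescence probability p_f."""

    subunits: int
    fluorescent_probability: float

    def __post_init__(self) -> None:
        if self.subunits < 1:
            raise ValueError("subunits must be >= 1")
        if not 0.0 <= self.fluorescent_probability <= 1.0:
            raise ValueError("fluorescent_probability must lie in [0, 1]")

    @property
    def normalized_brightness(self) -> float:
        """eps_n / eps_1 = 1 + (n - 1) * p_f."""
        return 1.0 + (self.subunits - 1) * self.fluorescent_probability


def fluorescence_probability(dimer_monomer_ratio: float) -> float:
    """Per-label fluorescence probability from a tandem-dimer:monomer ratio.

    Inverts eps_2/eps_1 = 1 + p_f.  Ratios below 1 (noise) clip to 0 with a
    warning; ratios above 2 are impossible under the model and raise.
    """
    if dimer_monomer_ratio > 2.0:
        raise ValueError(
            "a dimer:monomer brightness ratio above 2 is impossible for "
            "independent labels"
        )
    if dimer_monomer_ratio < 1.0:
        warnings.warn(
            "dimer:monomer ratio below 1; clipping fluorescence probability "
            "to 0",
            stacklevel=2,
        )
        return 0.0
    return dimer_monomer_ratio - 1.0


@dataclass(frozen=True)
class CorrectedBrightness:
    """Labeling-corrected relative brightness and which branch applied."""

    value: float
    corrected: bool

    def __float__(self) -> float:
        return self.value


def correct_relative_brightness(
    eps_app: float, eps_monomer: float, p_f: float
) -> CorrectedBrightness:
    """Correct a measured brightness for incomplete labeling.

    eps_norm = eps_app / eps_1; when the sample is brighter than the monomer
    the excess is deflated by the fluorescence probability:
    eps_corrected = 1 + (eps_norm - 1)/p_f.  Values at or below 1 pass through
    unchanged (they carry no oligomer signal to rescale).
    """
    if eps_monomer <= 0:
        raise ValueError("monomer brightness must be positive")
    eps_norm = eps_app / eps_monomer
    if eps_norm <= 1.0:
        return CorrectedBrightness(eps_norm, corrected=False)
    if not 0.0 < p_f <= 1.0:
        raise ValueError(
            "fluorescence probability must lie in (0, 1] to correct a "
            "brightness above the monomer"
        )
    return CorrectedBrightness(1.0 + (eps_norm - 1.0) / p_f, corrected=True)


def _check_n_oligomer(n_oligomer: int) -> None:
    if n_oligomer not in (2, 4):
        raise ValueError("two-state models are defined for dimers (2) or tetramers (4)")


def apparent_relative_brightness(x: float, n_oligomer: int) -> float:
    """Apparent relative brightness of a monomer/oligomer mixture.

    With oligomer fraction x (of particles) and ideal brightness ratio n:
    ((n^2 - 1) x + 1) / ((n - 1) x + 1) -- i.e. (3x+1)/(x+1) for a dimer and
    (15x+1)/(3x+1) for a tetramer.  Strictly increasing from 1 (x=0) to n
    (x=1).
    """
    _check_n_oligomer(n_oligomer)
    if not 0.0 <= x <= 1.0:
        raise ValueError("oligomer fraction must lie in [0, 1]")
    n = n_oligomer
    return ((n * n - 1.0) * x + 1.0) / ((n - 1.0) * x + 1.0)


def oligomer_fraction(eps_rel: float, n_oligomer: int) -> float:
    """Invert the two-state model: oligomer fraction from relative brightness.

    x = (e - 1) / ((n^2 - 1) - (n - 1) e).  Values slightly below 1 (noise)
    clip to 0 with a warning; values above n indicate model misspecification
    (e.g. movement artifacts or higher-order species) and raise.
    """
    _check_n_oligomer(n_oligomer)
    n = n_oligomer
    if eps_rel > n:
        raise ValueError(
            f"relative brightness {eps_rel} exceeds the pure-{n}-mer value {n}"
        )
    if eps_rel < 1.0:
        warnings.warn(
            "relative brightness below 1; clipping oligomer fraction to 0",
            stacklevel=2,
        )
        return 0.0
    return (eps_rel - 1.0) / ((n * n - 1.0) - (n - 1.0) * eps_rel)


def apparent_two_state(
    eps1: float, eps2: float, n1: float, n2: float
) -> tuple[float, float]:
    """Apparent (brightness, number) of a two-species mixture.

    eps_app is the intensity-weighted brightness
    (eps1^2 N1 + eps2^2 N2)/(eps1 N1 + eps2 N2) and N_app preserves the total
    intensity: eps_app * N_app = eps1 N1 + eps2 N2.
    """
    if min(eps1, eps2) < 0 or min(n1, n2) < 0:
        raise ValueError("brightnesses and numbers must be >= 0")
    total = eps1 * n1 + eps2 * n2
    if total == 0:
        raise ValueError("mixture carries no intensity")
    eps_app = (eps1**2 * n1 + eps2**2 * n2) / total
    return eps_app, total / eps_app


def protomer_concentration(
    eps_app: float,
    n_app: float,
    eps_monomer: float,
    volume_liters: float,
    labeling_efficiency: float = 1.0,
) -> float:
    """Monomer-equivalent ("protomer") concentration in nM.

    The total count rate eps_app * N_app equals eps_1 * N_1 for any mixture,
    so N_1 = eps_app * N_app / eps_1 protomers occupy the calibrated
    observation volume; dividing by the labeling efficiency counts unlabeled
    protomers as well.  Applied on raw brightnesses, before any normalization
    to relative units.
    """
    if eps_monomer <= 0 or volume_liters <= 0:
        raise ValueError("monomer brightness and volume must be positive")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labeling_efficiency must lie in (0, 1]")
    n1 = eps_app * n_app / eps_monomer
    molar = n1 / (volume_liters * AVOGADRO) / labeling_efficiency
    return molar * 1e9


@dataclass
class AggregationResult:
    """Per-cell brightness average after outlier-spot exclusion."""

    cell_mean: float
    used: np.ndarray
    excluded: np.ndarray

    def __float__(self) -> float:
        return self.cell_mean


def aggregate_cell(spot_brightnesses, min_spots: int = 3) -> AggregationResult:
    """Average spot brightnesses after a single-pass 1.5-sigma exclusion.

    The mean and sample (n-1) standard deviation are computed once over all
    spots; spots deviating from the mean by more than 1.5 sigma are dropped
    and the mean of the survivors is returned.  The single pass avoids the
    cascade that iterated trimming can produce on small spot counts.
    """
    eps = np.asarray(spot_brightnesses, dtype=float)
    if eps.size < min_spots:
        raise ValueError(f"need at least {min_spots} spots, got {eps.size}")
    mean = eps.mean()
    sigma = eps.std(ddof=1)
    if sigma == 0.0:
        keep = np.ones(eps.size, dtype=bool)
    else:
        keep = np.abs(eps - mean) <= 1.5 * sigma
    if not keep.any():  # impossible in a single pass for n >= 2
        raise AssertionError("1.5-sigma exclusion removed every spot")
    return AggregationResult(
        cell_mean=float(eps[keep].mean()),
        used=np.flatnonzero(keep),
        excluded=np.flatnonzero(~keep),
    )
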