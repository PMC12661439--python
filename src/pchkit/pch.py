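"""Semi-analytic photon counting histogram (PCH) model and fitter.

The PCH of a solution of diffusing fluorophores observed through a 3D-Gaussian
detection profile is built from the single-particle count distribution

    p1(k) = (1/V_ref) * int  Poisson(k; eps_bin * B(r)) dV,     k >= 1,

with the closure mass placed at k = 0.  Because the k >= 1 integrals converge
over all space, the population histogram for an open volume with mean particle
number N (referenced to V_ref) is the compound-Poisson distribution with
probability generating function exp(N * (G1(s) - 1)); mixtures multiply their
generating functions.  Detector dead time is applied as a first-order per-bin
binomial count-loss transform, matching the linear Mandel-Q calibration model
Q = 2 p_a - 2 I tau_d used to characterize the detector.

The reference volume is V_ref = int(B dV) and eps_bin is the per-bin count
rate of a molecule at the focus, so that mean(k) = eps_bin * N exactly
(intensity conservation; see :mod:`pchkit.geometry`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats

from .geometry import DEFAULT_PSF, GAMMA_2, PSFGeometry
from .trace import PCHistogram, PhotonCountTrace

__all__ = [
    "DetectorModel",
    "SpeciesComponent",
    "PCHFit",
    "QuadratureError",
    "single_particle_pch",
    "pch_expected",
    "mandel_q",
    "fit_pch",
]


class QuadratureError(RuntimeError):
    """Raised when the single-particle quadrature misses its tolerance."""


@dataclass(frozen=True)
class DetectorModel:
    """Detector artifact parameters.

    ``dead_time`` (s) is included in the fitted forward model; the afterpulsing
    probability is carried for simulation/calibration but is not part of the
    fitted model, since its effect on PCH fits is negligible at realistic
    values.
    """

    dead_time: float = 15e-9
    afterpulse_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if not 0.0 <= self.afterpulse_probability <= 1.0:
            raise ValueError("afterpulse_probability must lie in [0, 1]")


IDEAL_DETECTOR = DetectorModel(dead_time=0.0, afterpulse_probability=0.0)


@dataclass(frozen=True)
class SpeciesComponent:
    """One fluorescent species: brightness (cpsm) and mean number in V_ref."""

    brightness: float
    mean_number: float

    def __post_init__(self) -> None:
        if self.brightness < 0 or self.mean_number < 0:
            raise ValueError("brightness and mean_number must be >= 0")


@dataclass
class PCHFit:
    """Result of fitting a PCH with a 1- or 2-species model."""

    species: list[SpeciesComponent]
    reduced_chi_square: float
    k_max_used: int
    converged: bool
    n_pooled_bins: int
    message: str = ""
    sampling_frequency: float = 0.0

    @property
    def brightness(self) -> float:
        """Apparent brightness eps_app (cpsm); intensity-weighted for 2 species."""
        num = sum(s.brightness**2 * s.mean_number for s in self.species)
        den = sum(s.brightness * s.mean_number for s in self.species)
        return num / den if den > 0 else 0.0

    @property
    def number(self) -> float:
        """Apparent particle number N_app (total intensity / eps_app)."""
        den = self.brightness
        total = sum(s.brightness * s.mean_number for s in self.species)
        return total / den if den > 0 else 0.0


def _quadrature_nodes(eps_bin: float, n_nodes: int):
    """Gauss-Legendre nodes for int_0^inf sqrt(t) f(e^-t) dt via t = s^2."""
    t_max = max(math.log(max(eps_bin, 1.0)), 0.0) + 37.0
    s_max = math.sqrt(t_max)
    x, w = leggauss(n_nodes)
    s = 0.5 * s_max * (x + 1.0)
    w = 0.5 * s_max * w
    return s, w


def single_particle_pch(
    eps_bin: float,
    geometry: PSFGeometry = DEFAULT_PSF,
    k_max: int = 30,
    reference_volume: float | None = None,
    n_nodes: int = 400,
    tol: float = 1e-10,
) -> np.ndarray:
    """Count distribution of a single particle uniformly distributed in V_ref.

    Parameters
    ----------
    eps_bin : float
        Peak per-bin brightness (counts per bin for a molecule at the focus),
        i.e. epsilon / f_s.
    geometry : PSFGeometry
        Detection-profile dimensions.
    k_max : int
        Largest count evaluated; ``p[0]`` carries the closure mass.
    reference_volume : float, optional
        Volume (fL) to which the distribution is referenced.  Defaults to the
        profile-integrated volume, the convention under which the mean of the
        population histogram is eps_bin * N.

    Returns
    -------
    ndarray, shape (k_max + 1,)
    """
    if eps_bin < 0:
        raise ValueError("eps_bin must be >= 0")
    v_ref = geometry.reference_volume if reference_volume is None else reference_volume
    if v_ref < geometry.psf_volume * (1.0 - 1e-12):
        raise ValueError("reference volume must be at least the PSF volume")
    p = np.zeros(k_max + 1)
    if eps_bin == 0.0:
        p[0] = 1.0
        return p

    # Volume-shell decomposition of the 3D Gaussian: the volume enclosed by
    # the iso-surface B = e^-t is c_v * t^(3/2), so
    #   p1(k) = (3 c_v / 2 V_ref) * int_0^inf sqrt(t) Poi(k; eps_bin e^-t) dt
    # evaluated with t = s^2 to remove the sqrt endpoint singularity.
    c_v = (4.0 * math.pi / 3.0) * 2.0**-1.5
    c_v *= geometry.beam_waist**2 * geometry.axial_waist
    s, w = _quadrature_nodes(eps_bin, n_nodes)
    lam = eps_bin * np.exp(-(s**2))
    k = np.arange(1, k_max + 1)
    pmf = stats.poisson.pmf(k[:, None], lam[None, :])
    prefactor = (3.0 * c_v / (2.0 * v_ref)) * 2.0
    p[1:] = prefactor * (pmf @ (w * s**2))
    # quadrature ringing can leave O(1e-17) negatives in the deep tail
    np.clip(p, 0.0, None, out=p)

    # Self-check against the exact first moment, eps_bin * V_psf / V_ref.
    mean_exact = eps_bin * geometry.psf_volume / v_ref
    mean_num = float(k @ p[1:])
    tail = stats.poisson.sf(k_max, eps_bin)  # bound on mass beyond k_max
    if abs(mean_num - mean_exact) > tol * max(1.0, mean_exact) + 20.0 * k_max * tail:
        raise QuadratureError(
            f"single-particle quadrature off by {abs(mean_num - mean_exact):.3e}"
        )
    closure = 1.0 - p[1:].sum()
    if closure < -1e-12:
        # per-particle detection probability exceeds 1 in this volume; the
        # construction needs a larger reference volume (N rescales exactly)
        raise ValueError(
            "closure mass at k=0 is negative; use a reference_volume of at "
            f"least {v_ref * (1.0 - closure):.3g} fL for eps_bin={eps_bin:g}"
        )
    p[0] = max(closure, 0.0)
    return p


_deadtime_cache: dict[tuple[int, float], np.ndarray] = {}


def _deadtime_matrix(k_max: int, loss_per_pair: float) -> np.ndarray:
    """First-order dead-time transform matrix M[j, k] = P(observe j | k true).

    Each photon in a bin with k true photons is independently lost with
    probability (k - 1) * tau_d * f_s (the chance of falling inside the dead
    interval of another photon, to first order).
    """
    key = (k_max, round(loss_per_pair, 15))
    cached = _deadtime_cache.get(key)
    if cached is not None:
        return cached
    k = np.arange(k_max + 1)
    p_loss = np.clip((k - 1) * loss_per_pair, 0.0, 1.0)
    m = np.zeros((k_max + 1, k_max + 1))
    j = np.arange(k_max + 1)
    for kk in k:
        m[: kk + 1, kk] = stats.binom.pmf(kk - j[: kk + 1], kk, p_loss[kk])
    _deadtime_cache[key] = m
    return m


def pch_expected(
    species: list[SpeciesComponent] | SpeciesComponent,
    detector: DetectorModel = IDEAL_DETECTOR,
    sampling_frequency: float = 20_000.0,
    k_max: int | None = None,
    geometry: PSFGeometry = DEFAULT_PSF,
    tail_mass: float = 1e-12,
) -> np.ndarray:
    """Expected PCH (probability over k = 0..k_max) for a species mixture.

    ``k_max=None`` grows the support until the neglected tail is below
    ``tail_mass``; an explicit ``k_max`` that leaves more tail raises a
    ValueError asking for a larger support.
    """
    if isinstance(species, SpeciesComponent):
        species = [species]
    if not species:
        raise ValueError("at least one species is required")
    if sampling_frequency <= 0:
        raise ValueError("sampling_frequency must be positive")

    eps_bins = [s.brightness / sampling_frequency for s in species]
    mean = sum(e * s.mean_number for e, s in zip(eps_bins, species))
    var = mean + sum(
        GAMMA_2 * e**2 * s.mean_number for e, s in zip(eps_bins, species)
    )
    auto = k_max is None
    km = int(math.ceil(mean + 12.0 * math.sqrt(var) + 15)) if auto else int(k_max)

    for _attempt in range(6):
        n_fft = 2 * (km + 1)
        exponent = np.zeros(n_fft, dtype=complex)
        for e, s in zip(eps_bins, species):
            if s.mean_number == 0.0 or e == 0.0:
                continue
            # rescale the reference volume so the single-particle closure
            # mass stays positive; the compound distribution is exactly
            # invariant under (V_ref, N) -> (r V_ref, r N)
            r = max(1.0, 2.0 * e)
            p1 = np.zeros(n_fft)
            p1[: km + 1] = single_particle_pch(
                e, geometry, km, reference_volume=r * geometry.reference_volume
            )
            exponent += (r * s.mean_number) * (np.fft.fft(p1) - 1.0)
        p = np.fft.ifft(np.exp(exponent)).real
        p = np.clip(p[: km + 1], 0.0, None)
        tail = max(1.0 - p.sum(), 0.0)
        if tail <= tail_mass:
            break
        if not auto:
            raise ValueError(
                f"tail mass {tail:.2e} exceeds {tail_mass:.0e} at k_max={km}; "
                "increase k_max"
            )
        km *= 2
    else:
        raise QuadratureError("could not bound the tail mass")

    if detector.dead_time > 0.0:
        loss = detector.dead_time * sampling_frequency
        p = _deadtime_matrix(km, loss) @ p
    return p / p.sum()


def mandel_q(data) -> float:
    """Mandel Q = (variance - mean) / mean of the photon counts.

    Accepts a :class:`PhotonCountTrace`, a :class:`PCHistogram`, or a raw
    count array.  Variance uses denominator n (population moments).  Q is 0
    for Poisson light, negative under dead time, positive for molecular
    number fluctuations.
    """
    if isinstance(data, PCHistogram):
        m, v = data.mean, data.variance
    else:
        counts = data.counts if isinstance(data, PhotonCountTrace) else np.asarray(data)
        if counts.size == 0:
            raise ValueError("empty counts")
        m = float(counts.mean())
        v = float(counts.var())
    if m == 0:
        raise ValueError("Mandel Q is undefined for an all-zero trace")
    return (v - m) / m


def _pooled_edges(expected: np.ndarray, min_expected: float) -> list[tuple[int, int]]:
    """Pool the high-k tail so every pooled bin has expected >= min_expected."""
    n = expected.size
    edges: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        acc = expected[i]
        while acc < min_expected and j + 1 < n:
            j += 1
            acc += expected[j]
        if acc < min_expected and edges:
            # fold the deficient remainder into the previous pooled bin
            prev = edges.pop()
            edges.append((prev[0], n - 1))
            return edges
        edges.append((i, j))
        i = j + 1
    return edges


def _pool(values: np.ndarray, edges: list[tuple[int, int]]) -> np.ndarray:
    return np.array([values[a : b + 1].sum() for a, b in edges])


def fit_pch(
    histogram: PCHistogram,
    detector: DetectorModel = IDEAL_DETECTOR,
    n_species: int = 1,
    init: list[SpeciesComponent] | None = None,
    geometry: PSFGeometry = DEFAULT_PSF,
    min_expected: float = 5.0,
) -> PCHFit:
    """Recover molecular brightness and particle number from a PCH.

    Minimizes the Pearson chi-square between observed and expected bin
    frequencies (tail bins pooled to expected >= ``min_expected``) with a
    trust-region least-squares optimizer over log-parameters.  Initialization
    follows the method of moments: the dead-time-corrected Mandel Q gives
    eps_bin = Q / gamma_2, and the mean gives N; three fixed alternative
    starts are tried if the first does not converge.

    Returns a :class:`PCHFit`; ``converged=False`` flags a failed optimization
    rather than raising.
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    f_s = histogram.sampling_frequency
    total = histogram.total_bins
    if total < 100:
        raise ValueError("too few bins to fit a histogram")
    mean = histogram.mean
    if mean == 0:
        raise ValueError("cannot fit an all-zero histogram")

    q_obs = (histogram.variance - mean) / mean
    q_mol = q_obs + 2.0 * mean * f_s * detector.dead_time
    eps_bin0 = max(q_mol / GAMMA_2, 1e-4 * max(mean, 1e-3))
    n0 = mean / eps_bin0

    if init is not None:
        starts = [np.log(np.array(
            [[s.brightness / f_s, s.mean_number] for s in init]
        ).ravel())]
    elif n_species == 1:
        starts = [
            np.log([eps_bin0 * f, n0 / f]) for f in (1.0, 0.5, 2.0, 4.0)
        ]
    else:
        starts = [
            np.log([eps_bin0 * a, n0 / (2 * a), 2 * eps_bin0 * a, n0 / (4 * a)])
            for a in (0.75, 0.5, 1.5)
        ]

    observed = histogram.frequency.astype(float)

    def model_probs(theta: np.ndarray, k_support: int) -> np.ndarray:
        params = np.exp(theta)
        comps = [
            SpeciesComponent(params[2 * i] * f_s, params[2 * i + 1])
            for i in range(n_species)
        ]
        p = pch_expected(comps, detector, f_s, geometry=geometry)
        if p.size < k_support:
            p = np.pad(p, (0, k_support - p.size))
        return p

    best = None
    for theta0 in starts:
        # Pooling fixed from the start's expected distribution: deterministic
        # and keeps the objective continuous during optimization.
        try:
            p_init = model_probs(theta0, histogram.frequency.size)
        except (QuadratureError, ValueError):
            continue
        support = max(p_init.size, observed.size)
        obs = np.pad(observed, (0, support - observed.size))
        edges = _pooled_edges(p_init * total, min_expected)
        obs_pooled = _pool(obs, edges)

        def residuals(theta: np.ndarray) -> np.ndarray:
            p = model_probs(theta, support)[:support]
            e = _pool(p * total, edges)
            e = np.clip(e, 1e-12, None)
            return (obs_pooled - e) / np.sqrt(e)

        try:
            sol = optimize.least_squares(
                residuals, theta0, method="trf", x_scale="jac", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=300 * n_species,
            )
        except (QuadratureError, ValueError):
            continue
        chisq = float(sol.fun @ sol.fun)
        dof = max(len(edges) - 1 - 2 * n_species, 1)
        cand = (chisq / dof, sol, edges)
        if best is None or cand[0] < best[0]:
            best = cand
        if sol.success and cand[0] < 5.0:
            break

    if best is None:
        return PCHFit([], math.inf, 0, False, 0, "all starts failed", f_s)

    red_chisq, sol, edges = best
    params = np.exp(sol.x)
    comps = [
        SpeciesComponent(params[2 * i] * f_s, params[2 * i + 1])
        for i in range(n_species)
    ]
    pinned = bool(np.any(np.abs(sol.x) > 35.0))
    msg = sol.message + (" [parameter at extreme value]" if pinned else "")
    return PCHFit(
        species=comps,
        reduced_chi_square=red_chisq,
        k_max_used=edges[-1][1],
        converged=bool(sol.success and not pinned),
        n_pooled_bins=len(edges),
        message=msg,
        sampling_frequency=f_s,
    )
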