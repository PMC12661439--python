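"""The semi-analytic PCH model: moment identities, limits, and the fitter."""

import numpy as np
import pytest
from scipy import stats

from pchkit import (
    DetectorModel,
    PCHistogram,
    SpeciesComponent,
    fit_pch,
    mandel_q,
    pch_expected,
    single_particle_pch,
)
from pchkit.geometry import GAMMA_2
from pchkit.pch import IDEAL_DETECTOR
from pchkit.trace import PhotonCountTrace


class TestSingleParticle:
    def test_zero_brightness_is_certain_zero(self, geometry):
        p = single_particle_pch(0.0, geometry, k_max=10)
        assert p[0] == 1.0
        assert np.all(p[1:] == 0.0)

    @pytest.mark.parametrize("eps_bin", [0.01, 0.3, 1.0, 5.0, 25.0])
    def test_first_two_factorial_moments_match_closed_form(self, geometry, eps_bin):
        # mean = eps_bin * Vpsf/Vref; E[k(k-1)] = eps_bin^2 * int(B^2)/Vref
        k_max = int(3 * eps_bin + 40)
        # bright particles need a larger reference volume for a valid closure
        v = max(1.0, 2.0 * eps_bin) * geometry.reference_volume
        p = single_particle_pch(eps_bin, geometry, k_max=k_max, reference_volume=v)
        k = np.arange(k_max + 1)
        assert k @ p == pytest.approx(eps_bin * geometry.psf_volume / v, rel=1e-10)
        assert (k * (k - 1)) @ p == pytest.approx(
            eps_bin**2 * geometry.psf_volume_sq / v, rel=1e-8
        )
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_negative_closure_mass_instructs_larger_volume(self, geometry):
        with pytest.raises(ValueError, match="reference_volume"):
            single_particle_pch(25.0, geometry, k_max=120)

    def test_larger_reference_volume_dilutes_nonzero_counts(self, geometry):
        p1 = single_particle_pch(1.0, geometry, k_max=20)
        p2 = single_particle_pch(
            1.0, geometry, k_max=20, reference_volume=2 * geometry.reference_volume
        )
        assert np.allclose(p2[1:], p1[1:] / 2.0, rtol=1e-12)

    def test_reference_volume_below_psf_volume_rejected(self, geometry):
        with pytest.raises(ValueError):
            single_particle_pch(
                1.0, geometry, k_max=5, reference_volume=0.5 * geometry.psf_volume
            )


class TestPCHExpected:
    def test_normalized_and_moments(self, geometry):
        sp = SpeciesComponent(20_000.0, 2.0)
        p = pch_expected(sp, IDEAL_DETECTOR, 20_000.0, geometry=geometry)
        k = np.arange(p.size)
        mean = k @ p
        var = ((k - mean) ** 2) @ p
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        # mean = eps_bin * N; molecular Mandel Q = gamma_2 * eps_bin
        assert mean == pytest.approx(2.0, rel=1e-6)
        assert (var - mean) / mean == pytest.approx(GAMMA_2 * 1.0, rel=1e-6)

    def test_shot_noise_limit_is_poisson(self, geometry):
        # eps -> 0 with N*eps fixed: molecular fluctuations vanish
        p = pch_expected(
            SpeciesComponent(2.0, 20_000.0), IDEAL_DETECTOR, 20_000.0,
            geometry=geometry,
        )
        k = np.arange(p.size)
        mean = k @ p
        assert np.abs(p - stats.poisson.pmf(k, mean)).max() < 1e-4
        var = ((k - mean) ** 2) @ p
        assert abs((var - mean) / mean) < 1e-4

    def test_mixture_moments_additive(self, geometry):
        comps = [SpeciesComponent(20_000.0, 1.0), SpeciesComponent(40_000.0, 0.5)]
        p = pch_expected(comps, IDEAL_DETECTOR, 20_000.0, geometry=geometry)
        k = np.arange(p.size)
        assert k @ p == pytest.approx(1.0 * 1.0 + 2.0 * 0.5, rel=1e-8)

    def test_single_species_is_super_poissonian(self, geometry):
        p = pch_expected(
            SpeciesComponent(30_000.0, 1.0), IDEAL_DETECTOR, 20_000.0,
            geometry=geometry,
        )
        k = np.arange(p.size)
        mean = k @ p
        var = ((k - mean) ** 2) @ p
        assert var > mean

    def test_dead_time_reduces_mean_and_q(self, geometry):
        sp = SpeciesComponent(40_000.0, 3.0)
        p0 = pch_expected(sp, IDEAL_DETECTOR, 20_000.0, geometry=geometry)
        p1 = pch_expected(
            sp, DetectorModel(dead_time=1e-6), 20_000.0, geometry=geometry
        )

        def moments(p):
            k = np.arange(p.size)
            m = k @ p
            return m, ((k - m) ** 2) @ p

        m0, v0 = moments(p0)
        m1, v1 = moments(p1)
        assert m1 < m0
        assert (v1 - m1) / m1 < (v0 - m0) / m0

    def test_explicit_k_max_too_small_rejected(self, geometry):
        with pytest.raises(ValueError, match="k_max"):
            pch_expected(
                SpeciesComponent(100_000.0, 5.0), IDEAL_DETECTOR, 20_000.0,
                k_max=5, geometry=geometry,
            )


class TestMandelQ:
    def test_constant_counts_give_minus_one(self):
        assert mandel_q(np.array([1, 1, 1, 1])) == pytest.approx(-1.0)

    def test_all_zero_trace_undefined(self):
        with pytest.raises(ValueError):
            mandel_q(np.zeros(100, dtype=int))

    def test_trace_and_histogram_agree(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, 10_000)
        trace = PhotonCountTrace(counts, 20_000.0)
        assert mandel_q(trace) == pytest.approx(
            mandel_q(PCHistogram.from_trace(trace)), rel=1e-12
        )


class TestFitPCH:
    def test_self_consistency_exact_recovery(self, geometry):
        # histogram generated by the model itself -> parameters recovered
        sp = SpeciesComponent(25_000.0, 1.5)
        det = DetectorModel(dead_time=15e-9)
        p = pch_expected(sp, det, 20_000.0, geometry=geometry)
        freq = np.round(p * 4e6).astype(np.int64)
        fit = fit_pch(PCHistogram(freq, 20_000.0), det, geometry=geometry)
        assert fit.converged
        assert fit.brightness == pytest.approx(25_000.0, rel=1e-3)
        assert fit.number == pytest.approx(1.5, rel=1e-3)

    def test_two_species_histogram_single_fit_gives_weighted_brightness(
        self, geometry
    ):
        # (eps, N) + (2 eps, N): apparent brightness = 5/3 eps
        comps = [SpeciesComponent(20_000.0, 1.0), SpeciesComponent(40_000.0, 1.0)]
        p = pch_expected(comps, IDEAL_DETECTOR, 20_000.0, geometry=geometry)
        freq = np.round(p * 6e5).astype(np.int64)
        fit = fit_pch(PCHistogram(freq, 20_000.0), DetectorModel(0.0), geometry=geometry)
        assert fit.converged
        assert fit.brightness / 20_000.0 == pytest.approx(5.0 / 3.0, rel=0.05)
        # total intensity is conserved regardless of the model mismatch
        assert fit.brightness * fit.number == pytest.approx(
            20_000.0 * 1.0 + 40_000.0 * 1.0, rel=0.01
        )

    def test_invalid_inputs(self, geometry):
        hist = PCHistogram(np.array([50_000, 1_000]), 20_000.0)
        with pytest.raises(ValueError):
            fit_pch(hist, n_species=3)
        with pytest.raises(ValueError):
            fit_pch(PCHistogram(np.array([10, 5]), 20_000.0))  # too few bins
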