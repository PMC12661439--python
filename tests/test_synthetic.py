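"""Monte-Carlo generators: limits, detector artifacts, drift, kinetics tables."""

import numpy as np
import pytest
from scipy import stats

from pchkit import (
    PCHistogram,
    SimulationConfig,
    Species,
    SpeciesComponent,
    apply_detector,
    mandel_q,
    pch_expected,
    simulate_bleach_trace,
    simulate_diffusion_trace,
    simulate_dissociation_series,
    simulate_labeling_timecourse,
    simulate_snapshot_counts,
)
from pchkit.pch import IDEAL_DETECTOR
from pchkit.synthetic import BoxSizingError, DetectorSaturationError
from pchkit.trace import PhotonCountTrace

from conftest import chi_square_pvalue


def single_species_config(seed, eps, n_ref, nref_to_box, **kwargs):
    return SimulationConfig(
        seed=seed, species=(Species(eps, nref_to_box(n_ref)),), dead_time=0.0,
        **kwargs,
    )


class TestSnapshot:
    def test_zero_brightness_all_zero(self, nref_to_box):
        cfg = single_species_config(1, 0.0, 5.0, nref_to_box)
        trace = simulate_snapshot_counts(cfg, 1000)
        assert np.all(trace.counts == 0)

    def test_zero_particles_all_zero(self):
        cfg = SimulationConfig(seed=1, species=(Species(20_000.0, 0.0),))
        assert np.all(simulate_snapshot_counts(cfg, 1000).counts == 0)

    def test_seed_reproducibility_bit_identical(self, nref_to_box):
        cfg = single_species_config(77, 20_000.0, 2.0, nref_to_box)
        a = simulate_snapshot_counts(cfg, 5000)
        b = simulate_snapshot_counts(cfg, 5000)
        assert np.array_equal(a.counts, b.counts)

    def test_mean_matches_closed_form(self, nref_to_box):
        # mean per bin = eps_bin * N_ref within sampling error
        cfg = single_species_config(3, 20_000.0, 4.0, nref_to_box)
        trace = simulate_snapshot_counts(cfg, 200_000)
        m = trace.counts.mean()
        sd = trace.counts.std() / np.sqrt(len(trace))
        assert abs(m - 4.0) < 4 * sd

    def test_poisson_superposition_two_halves_equal_one_species(self, nref_to_box):
        half = nref_to_box(1.5)
        cfg2 = SimulationConfig(
            seed=10, dead_time=0.0,
            species=(Species(20_000.0, half), Species(20_000.0, half)),
        )
        trace = simulate_snapshot_counts(cfg2, 300_000)
        p = pch_expected(
            SpeciesComponent(20_000.0, 3.0), IDEAL_DETECTOR, 20_000.0
        )
        assert chi_square_pvalue(PCHistogram.from_trace(trace), p) > 0.01

    def test_labeling_scheme_reproduces_brightness_model(self, nref_to_box):
        # an n-mer population with per-label p_f has apparent brightness
        # (1 + (n-1) p_f) times the per-label brightness
        n, p_f = 2, 0.7
        cfg = SimulationConfig(
            seed=17, dead_time=0.0,
            species=(Species(20_000.0, nref_to_box(2.0), p_f, n),),
        )
        trace = simulate_snapshot_counts(cfg, 300_000)
        counts = trace.counts.astype(float)
        mean = counts.mean()
        q = mandel_q(trace)
        # intensity-weighted brightness from the first two moments:
        # Q = gamma2 * eps_app_bin  for any species mixture
        from pchkit.geometry import GAMMA_2

        eps_app = q / GAMMA_2  # counts/bin
        expected = (1.0 + (n - 1) * p_f) * 1.0  # per-label eps_bin = 1
        assert eps_app == pytest.approx(expected, rel=0.05)
        assert mean == pytest.approx(n * p_f * 1.0 * 2.0, rel=0.02)

    def test_box_too_small_rejected(self, geometry):
        with pytest.raises(BoxSizingError):
            SimulationConfig(
                seed=0,
                box_lengths=(
                    4 * geometry.beam_waist,
                    4 * geometry.beam_waist,
                    4 * geometry.axial_waist,
                ),
            )

    def test_n_bins_must_be_positive(self, nref_to_box):
        cfg = single_species_config(1, 20_000.0, 1.0, nref_to_box)
        with pytest.raises(ValueError):
            simulate_snapshot_counts(cfg, 0)


class TestDiffusion:
    def test_marginal_matches_snapshot_model(self, nref_to_box):
        # One-bin marginal of the Brownian trace equals the semi-analytic
        # PCH.  Pool several independent traces: each trace holds its
        # (Poisson-drawn) particle number fixed, and only the pool restores
        # the open-volume number statistics; a very large D decorrelates
        # successive bins so the chi-square count model applies.
        counts = []
        with pytest.warns(UserWarning, match="under-sampled"):
            for seed in range(20):
                cfg = single_species_config(
                    300 + seed, 20_000.0, 2.0, nref_to_box, duration=0.25,
                    diffusion_coefficient=2e4,
                )
                counts.append(simulate_diffusion_trace(cfg).counts)
        pooled = PhotonCountTrace(np.concatenate(counts), 20_000.0)
        p = pch_expected(SpeciesComponent(20_000.0, 2.0), IDEAL_DETECTOR, 20_000.0)
        assert chi_square_pvalue(PCHistogram.from_trace(pooled), p) > 0.01

    def test_zero_particles_all_zero(self):
        cfg = SimulationConfig(
            seed=2, duration=0.5, species=(Species(20_000.0, 0.0),)
        )
        assert np.all(simulate_diffusion_trace(cfg).counts == 0)

    def test_linear_drift_decile_ratio(self, nref_to_box):
        # drift_slope 0.2: last-decile mean ~ 1.19/1.01 ~ 1.18x the first.
        # Slow molecular number fluctuations dominate single-trace decile
        # means, so average three traces and also check the pooled linear
        # drift estimate (which uses every bin).
        firsts, lasts, drifts = [], [], []
        for seed in (31, 32, 33):
            cfg = single_species_config(
                seed, 8_000.0, 3.0, nref_to_box, duration=60.0,
                drift_slope=0.2, sampling_frequency=1_000.0,
            )
            trace = simulate_diffusion_trace(cfg)
            n = len(trace) // 10
            firsts.append(trace.counts[:n].mean())
            lasts.append(trace.counts[-n:].mean())
            per_s = trace.counts.reshape(60, -1).mean(axis=1)
            slope, intercept = np.polyfit(np.arange(60) + 0.5, per_s, 1)
            drifts.append(slope * 60.0 / per_s.mean())
        assert np.mean(lasts) / np.mean(firsts) == pytest.approx(
            1.19 / 1.01, rel=0.06
        )
        assert np.mean(drifts) == pytest.approx(0.2, abs=0.08)

    def test_undersampling_warns(self, nref_to_box):
        cfg = single_species_config(
            5, 20_000.0, 1.0, nref_to_box, duration=0.01,
            diffusion_coefficient=5_000.0,
        )
        with pytest.warns(UserWarning, match="under-sampled"):
            simulate_diffusion_trace(cfg)


class TestDetector:
    def test_identity_when_ideal(self):
        trace = PhotonCountTrace(np.array([0, 1, 5, 2]), 20_000.0)
        out = apply_detector(trace, 0.0, 0.0, seed=1)
        assert np.array_equal(out.counts, trace.counts)

    def test_dead_time_mandel_q_constant_source(self):
        # I = 1e6 counts/s, tau_d = 15 ns -> Q ~ -2 I tau_d = -0.03
        rng = np.random.default_rng(8)
        ideal = PhotonCountTrace(rng.poisson(50.0, 1_000_000), 20_000.0)
        out = apply_detector(ideal, 15e-9, 0.0, seed=9)
        assert mandel_q(out) == pytest.approx(-0.03, abs=0.004)

    def test_afterpulsing_mandel_q(self):
        # p_a = 0.01, Poisson input -> Q ~ 2 p_a = 0.02
        rng = np.random.default_rng(12)
        ideal = PhotonCountTrace(rng.poisson(5.0, 1_000_000), 20_000.0)
        out = apply_detector(ideal, 0.0, 0.01, seed=13)
        assert mandel_q(out) == pytest.approx(0.02, abs=0.004)

    def test_saturation_raises(self):
        trace = PhotonCountTrace(np.array([200_000]), 20_000.0)
        with pytest.raises(DetectorSaturationError):
            apply_detector(trace, 15e-9, 0.0, seed=1)


class TestKineticsTables:
    def test_dissociation_noiseless_t0_and_half_life_point(self):
        # x0=1, dimer: at t = tau ln 2 the fraction is 1/2 -> brightness 5/3
        tau = 10.0
        t = np.array([0.0, tau * np.log(2.0), 50.0])
        df = simulate_dissociation_series(1.0, tau, 2, t, noise_sd=0.0)
        assert df["relative_brightness"].iloc[0] == pytest.approx(2.0)
        assert df["relative_brightness"].iloc[1] == pytest.approx(5.0 / 3.0)

    def test_dissociation_full_dissociation_limit(self):
        df = simulate_dissociation_series(1.0, 5.0, 2, [1e4], noise_sd=0.0)
        assert df["relative_brightness"].iloc[0] == pytest.approx(1.0)

    def test_dissociation_invalid_tau(self):
        with pytest.raises(ValueError):
            simulate_dissociation_series(0.5, -1.0, 2, [0.0, 1.0])

    def test_bleach_closed_form(self):
        df = simulate_bleach_trace(0.1, [0.0, 10.0], noise_sd=0.0)
        assert df["normalized_intensity"].iloc[0] == pytest.approx(1.0)
        assert df["normalized_intensity"].iloc[1] == pytest.approx(np.exp(-1.0))

    def test_bleach_zero_rate_constant(self):
        df = simulate_bleach_trace(0.0, np.linspace(0, 30, 10), noise_sd=0.0)
        assert np.allclose(df["normalized_intensity"], 1.0)

    def test_bleach_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_bleach_trace(-0.1, [0.0, 1.0])

    def test_labeling_normalized_plateau(self):
        df = simulate_labeling_timecourse(rate=2.0, times=(1, 2, 4, 8, 24))
        assert df["ratio"].max() == pytest.approx(1.0)
        # half-time point: rate = ln2/2 at t = 2 h gives half of plateau
        df2 = simulate_labeling_timecourse(
            rate=np.log(2) / 2.0, times=(2.0, 1000.0), noise_sd=0.0
        )
        assert df2["ratio"].iloc[0] == pytest.approx(0.5, rel=1e-6)

    def test_seeded_noise_reproducible(self):
        a = simulate_dissociation_series(0.8, 5.0, 2, np.arange(9.0), 0.05, seed=4)
        b = simulate_dissociation_series(0.8, 5.0, 2, np.arange(9.0), 0.05, seed=4)
        assert np.array_equal(a["relative_brightness"], b["relative_brightness"])
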