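"""Synthetic cohort generator: truth distributions, curves, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubemech.invert import ParamRanges
from tubemech.synth import (
    GROWING,
    NON_GROWING,
    IndentationProtocol,
    SensorSpec,
    SpeciesParams,
    TubeSample,
    UnreachableForceError,
    apex_attenuation,
    empirical_truth_params,
    sample_cohort,
    sample_truth_pairs,
    simulate_cohort,
    synthesize_curve,
    truth_params_for_group,
    window_slope_factor,
)


class TestEmpiricalTruthParams:
    def test_growing_loading_closed_form(self):
        mu, sigma = empirical_truth_params(2.20, 1.73)
        assert mu == pytest.approx(math.log(1.73))
        assert sigma == pytest.approx(math.sqrt(2 * math.log(2.20 / 1.73)))

    def test_degenerate_point_mass(self):
        mu, sigma = empirical_truth_params(3.0, 3.0)
        assert sigma == 0.0
        assert math.exp(mu) == pytest.approx(3.0)

    def test_mean_below_median_rejected(self):
        with pytest.raises(ValueError):
            empirical_truth_params(1.5, 2.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        median=st.floats(0.05, 50.0),
        ratio=st.floats(1.0, 3.0),
    )
    def test_moment_relations_roundtrip(self, median, ratio):
        mean = median * ratio
        mu, sigma = empirical_truth_params(mean, median)
        assert math.exp(mu) == pytest.approx(median, rel=1e-12)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-12)

    @pytest.mark.parametrize("mean,median", [(2.20, 1.73), (3.28, 2.98)])
    def test_monte_carlo_moments_match(self, mean, median):
        """10^5 lognormal draws reproduce the inputs within 3 MC SEs."""
        mu, sigma = empirical_truth_params(mean, median)
        rng = np.random.default_rng(123)
        n = 100_000
        x = rng.lognormal(mu, sigma, n)
        sd = x.std(ddof=1)
        assert abs(x.mean() - mean) < 3 * sd / math.sqrt(n)
        # SE of the sample median of a lognormal: 1/(2 f(m) sqrt(n))
        dens = math.exp(-(0.0) ** 2) / (median * sigma * math.sqrt(2 * math.pi))
        se_med = 1.0 / (2 * dens * math.sqrt(n))
        assert abs(np.median(x) - median) < 3 * se_med


class TestTruthPairs:
    @pytest.mark.parametrize("stats", [GROWING, NON_GROWING])
    def test_calibrated_means_and_ordering(self, stats):
        params = truth_params_for_group(stats)
        rng = np.random.default_rng(7)
        n = 200_000
        kl, ku = sample_truth_pairs(params, n, rng)
        assert np.all(ku >= kl), "hysteresis direction must hold for every tube"
        se_l = kl.std(ddof=1) / math.sqrt(n)
        se_u = ku.std(ddof=1) / math.sqrt(n)
        assert abs(kl.mean() - stats.load_mean) < 3 * se_l
        assert abs(ku.mean() - stats.unload_mean) < 3 * se_u
        if stats.load_median is not None:
            assert np.median(kl) == pytest.approx(stats.load_median, rel=0.02)

    def test_pairs_are_correlated(self):
        params = truth_params_for_group(GROWING, rho=0.8)
        kl, ku = sample_truth_pairs(params, 50_000, np.random.default_rng(3))
        r = np.corrcoef(np.log(kl), np.log(ku))[0, 1]
        assert r > 0.6


class TestSampleCohort:
    def test_lily_diameter_mean_within_3se(self, lily):
        tubes = sample_cohort(lily, 40, seed=11)
        mean_d = np.mean([t.diameter for t in tubes])
        assert abs(mean_d - 17.4) < 3 * 2.5 / math.sqrt(40)

    def test_zero_sd_gives_constant_diameter(self):
        species = SpeciesParams("fixed", 17.4, 0.0)
        tubes = sample_cohort(species, 10, seed=0)
        assert all(t.diameter == 17.4 for t in tubes)

    def test_same_seed_same_cohort(self, lily):
        a = sample_cohort(lily, 12, seed=42)
        b = sample_cohort(lily, 12, seed=42)
        assert a == b

    def test_invalid_ranges_rejected(self, lily):
        with pytest.raises(ValueError):
            sample_cohort(lily, 5, ranges=ParamRanges(t_range=(0.3, 0.1)))

    def test_thickness_and_turgor_within_ranges(self, lily):
        rng = ParamRanges(t_range=(0.15, 0.25), p_range=(0.2, 0.3))
        tubes = sample_cohort(lily, 50, ranges=rng, seed=5)
        assert all(0.15 <= t.wall_thickness <= 0.25 for t in tubes)
        assert all(0.2 <= t.turgor <= 0.3 for t in tubes)

    def test_mechanistic_mode_requires_and_uses_modulus(self, lily):
        with pytest.raises(ValueError):
            sample_cohort(lily, 3, mode="mechanistic")
        tubes = sample_cohort(lily, 3, mode="mechanistic", E_true=90.0, seed=1)
        assert all(t.E_true == 90.0 for t in tubes)
        assert all(t.k_unload_true > t.k_load_true for t in tubes)


class TestApexAttenuation:
    @pytest.mark.parametrize(
        "dist,expected",
        [(10.0, 1.0), (8.7, 1.0), (0.0, 0.0), (4.35, 0.25)],
    )
    def test_cosine_squared_projection(self, dist, expected):
        assert apex_attenuation(dist, 8.7) == pytest.approx(expected)

    def test_vectorized_and_monotone(self):
        d = np.linspace(0, 20, 50)
        f = apex_attenuation(d, 8.7)
        assert np.all(np.diff(f) >= 0)
        assert np.all((0 <= f) & (f <= 1))


class TestSynthesizeCurve:
    def test_series_spring_raw_slope(self, protocol):
        """k_true = 3, k_sensor = 6: raw contact slope is the harmonic sum 2."""
        tube = TubeSample("t", 17.4, 0.2, 0.2, True, 3.0, 4.0)
        sensor = SensorSpec(k_sensor=6.0, force_noise_sd_nN=0.0, capillary_slope=0.0)
        c = synthesize_curve(tube, sensor, protocol, 1.0, beta=0.0, seed=0)
        i_top = int(np.argmax(c.force))
        mask = (c.z_stage > 1.2) & (np.arange(c.force.size) <= i_top)
        slope = np.polyfit(c.z_stage[mask], c.force[mask], 1)[0]
        assert slope == pytest.approx(1.0 / (1 / 3.0 + 1 / 6.0), rel=1e-9)

    def test_rigid_sensor_limit(self, protocol):
        tube = TubeSample("t", 17.4, 0.2, 0.2, True, 3.0, 4.0)
        sensor = SensorSpec(k_sensor=1e9, force_noise_sd_nN=0.0, capillary_slope=0.0)
        c = synthesize_curve(tube, sensor, protocol, 1.0, beta=0.0, seed=0)
        i_top = int(np.argmax(c.force))
        mask = (c.z_stage > 1.2) & (np.arange(c.force.size) <= i_top)
        slope = np.polyfit(c.z_stage[mask], c.force[mask], 1)[0]
        assert slope == pytest.approx(3.0, rel=1e-6)

    def test_max_force_matches_protocol(self, tube, noisy_sensor, protocol):
        c = synthesize_curve(tube, noisy_sensor, protocol, 1.5, beta=0.1, seed=4)
        assert abs(c.force.max() - protocol.max_force) < 3 * noisy_sensor.force_noise_sd_uN + 0.02

    def test_unreachable_max_force_reported(self, quiet_sensor):
        protocol = IndentationProtocol(max_travel=5.0)
        soft = TubeSample("s", 17.4, 0.2, 0.2, True, 0.1, 0.15)
        with pytest.raises(UnreachableForceError):
            synthesize_curve(soft, quiet_sensor, protocol, 1.0, seed=0)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            TubeSample("bad", 17.4, 0.2, 0.2, True, -1.0, 1.0)

    def test_hysteresis_ordering_violates(self):
        with pytest.raises(ValueError):
            TubeSample("bad", 17.4, 0.2, 0.2, True, 2.0, 1.0)


class TestWindowSlopeFactor:
    def test_linear_curve_has_unit_factor(self):
        assert window_slope_factor(0.0, 0.2, "load") == 1.0
        assert window_slope_factor(0.0, 0.2, "unload") == 1.0

    def test_loading_factor_exceeds_unloading(self):
        """Curvature inflates the top-window slope much more on loading
        (window far from contact) than on unloading (window at its start)."""
        f_l = window_slope_factor(0.1, 0.2, "load")
        f_u = window_slope_factor(0.1, 0.2, "unload")
        assert f_l > f_u > 1.0
        assert f_l == pytest.approx(1.1814, abs=1e-3)

    @settings(max_examples=60, derandomize=True)
    @given(beta=st.floats(0.0, 0.5), w=st.floats(0.05, 0.6))
    def test_factors_bounded(self, beta, w):
        for phase in ("load", "unload"):
            f = window_slope_factor(beta, w, phase)
            assert 1.0 <= f <= 1.0 + beta * 2.0


class TestSimulateCohort:
    def test_fixed_seed_reproducible_bitwise(self, lily):
        c1, m1 = simulate_cohort(lily, "growing", n_tubes=4, m_indent=8, seed=9)
        c2, m2 = simulate_cohort(lily, "growing", n_tubes=4, m_indent=8, seed=9)
        assert m1 == m2
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.force, b.force)
            np.testing.assert_array_equal(a.z_stage, b.z_stage)

    def test_default_sizes_match_group_statistics(self, lily):
        curves, manifest = simulate_cohort(lily, "growing", seed=2)
        assert len(manifest["tubes"]) == 19
        assert len(curves) + manifest["n_unreachable_skipped"] == 135

    def test_manifest_answer_key_complete(self, lily):
        curves, manifest = simulate_cohort(lily, "growing", n_tubes=3, m_indent=6, seed=1)
        assert manifest["schema"] == "tubemech-cohort/1"
        ids = {t["id"] for t in manifest["tubes"]}
        assert all(e["tube_id"] in ids for e in manifest["curves"])
        assert all(t["k_unload_true_N_per_m"] >= t["k_load_true_N_per_m"]
                   for t in manifest["tubes"])

    def test_excessive_capillary_slope_rejected(self, lily):
        sensor = SensorSpec(capillary_slope=1.0)
        with pytest.raises(ValueError, match="capillary"):
            simulate_cohort(lily, "growing", n_tubes=4, m_indent=8, seed=0,
                            sensor=sensor)

    def test_shank_distances_on_shank(self, lily):
        _, manifest = simulate_cohort(lily, "growing", n_tubes=4, m_indent=12, seed=3)
        assert all(e["distance_from_tip_um"] >= 50.0 for e in manifest["curves"])
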