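"""Curve processing: contact detection, sensor cancellation, statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tubemech.curves import (
    NoContactError,
    ProcessingError,
    apex_profile,
    apparent_stiffness,
    cancel_sensor,
    cohort_statistics,
    compare_groups,
    detect_contact,
    process_cohort,
    process_curve,
)
from tubemech.synth import (
    IndentationProtocol,
    RawCurve,
    SensorSpec,
    TubeSample,
    simulate_cohort,
    synthesize_curve,
)

from conftest import spawn_seeds


def make_tube(k_load=2.2, k_unload=3.3):
    return TubeSample("t0", 17.4, 0.2, 0.2, True, k_load, k_unload)


class TestDetectContact:
    def test_noiseless_contact_within_one_sample(self, quiet_sensor, protocol):
        c = synthesize_curve(make_tube(), quiet_sensor, protocol, 1.4, beta=0.0, seed=0)
        dz = protocol.speed / protocol.sample_rate
        contact = detect_contact(c)
        assert abs(contact.z0 - 1.4) <= dz

    def test_noisy_contact_within_three_samples(self, noisy_sensor, protocol):
        """Answer-key comparison across seeded noisy curves."""
        dz = protocol.speed / protocol.sample_rate
        errs = []
        for seed in spawn_seeds(2024, 100):
            rng = np.random.default_rng(seed)
            z0 = float(rng.uniform(1.0, 2.0))
            c = synthesize_curve(make_tube(), noisy_sensor, protocol, z0,
                                 beta=0.1, seed=rng)
            errs.append(abs(detect_contact(c).z0 - z0))
        assert np.max(errs) <= 3 * dz

    def test_all_baseline_curve_raises(self):
        rng = np.random.default_rng(0)
        z = np.concatenate([np.linspace(0, 5, 600), np.linspace(5, 0, 600)])
        f = rng.normal(0, 0.01, z.size)
        curve = RawCurve(time=np.arange(z.size) / 500.0, z_stage=z, force=f)
        with pytest.raises(NoContactError):
            detect_contact(curve)

    def test_short_curve_rejected(self):
        z = np.concatenate([np.linspace(0, 1, 40), np.linspace(1, 0, 40)])
        curve = RawCurve(time=np.arange(80) / 500.0, z_stage=z,
                         force=np.zeros(80))
        with pytest.raises(ProcessingError):
            detect_contact(curve)


class TestCancelSensor:
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 5.0, 50.0])
    def test_exact_recovery_on_linear_noiseless_curves(self, protocol, ratio):
        """Series-spring construction is inverted exactly: recovered k
        matches truth to < 0.1% for k_sensor/k_true from 0.5 to 50."""
        k_true = 2.0
        sensor = SensorSpec(k_sensor=ratio * k_true, force_noise_sd_nN=0.0,
                            capillary_slope=0.0)
        c = synthesize_curve(make_tube(k_true, 1.5 * k_true), sensor, protocol,
                             1.2, beta=0.0, seed=0)
        rec = process_curve(c)
        assert rec["k_load_N_per_m"] == pytest.approx(k_true, rel=1e-3)
        assert rec["k_unload_N_per_m"] == pytest.approx(1.5 * k_true, rel=1e-3)

    def test_rigid_sensor_is_identity_and_idempotent(self, quiet_sensor, protocol):
        c = synthesize_curve(make_tube(), quiet_sensor, protocol, 1.0, beta=0.0,
                             seed=0)
        contact = detect_contact(c)
        once = cancel_sensor(c, contact, np.inf)
        np.testing.assert_allclose(
            once.delta, c.z_stage[contact.index:] - contact.z0
        )
        # re-applying the null correction to the already-corrected curve
        again = RawCurve(
            time=c.time[contact.index:],
            z_stage=c.z_stage[contact.index:],
            force=c.force[contact.index:],
        )
        contact2 = detect_contact(c)
        twice = cancel_sensor(c, contact2, np.inf)
        np.testing.assert_allclose(once.delta, twice.delta)
        np.testing.assert_allclose(once.force, twice.force)

    def test_wrong_sensor_stiffness_flagged(self, quiet_sensor, protocol):
        """Overcorrecting with a too-soft assumed sensor bends delta negative."""
        c = synthesize_curve(make_tube(), quiet_sensor, protocol, 1.0, beta=0.0,
                             seed=0)
        contact = detect_contact(c)
        proc = cancel_sensor(c, contact, 0.5)  # true k_sensor is 10
        assert proc.meta["suspect_correction"]


class TestApparentStiffness:
    @pytest.mark.parametrize("w", [0.1, 0.2, 0.4])
    def test_exact_line(self, w):
        delta = np.linspace(0, 2.5, 400)
        force = 2.0 * delta
        k, r2, n = apparent_stiffness(delta, force, window_fraction=w)
        assert k == pytest.approx(2.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)
        assert n >= 10

    def test_window_too_small_rejected(self):
        delta = np.linspace(0, 1, 30)
        with pytest.raises(ProcessingError):
            apparent_stiffness(delta, 2 * delta, window_fraction=0.01)

    @pytest.mark.parametrize("beta", [0.05, 0.1, 0.3])
    def test_curved_loading_recovers_calibrated_truth(self, quiet_sensor,
                                                      protocol, beta):
        """The analytic window factor built into the generator makes the
        top-window OLS slope equal the nominal truth for any curvature."""
        c = synthesize_curve(make_tube(), quiet_sensor, protocol, 1.2,
                             beta=beta, seed=0)
        rec = process_curve(c)
        assert rec["k_load_N_per_m"] == pytest.approx(2.2, rel=0.01)
        assert rec["k_unload_N_per_m"] == pytest.approx(3.3, rel=0.01)

    def test_hysteretic_curves_keep_phase_ordering(self, noisy_sensor, protocol, lily):
        """Measured unloading stiffness >= loading stiffness (up to noise)
        across seeded curves, matching the generated truth ordering."""
        curves, manifest = simulate_cohort(lily, "growing", n_tubes=20,
                                           m_indent=100, seed=31)
        records = process_cohort(curves)
        assert np.all(
            records["k_unload_N_per_m"] >= records["k_load_N_per_m"] * 0.99
        )


class TestCapillaryNeglect:
    def test_one_percent_capillary_biases_k_below_two_percent(self, protocol):
        """The rationale for neglecting the capillary background: a slope
        at 1% of the sample stiffness perturbs k by under 2%."""
        tube = make_tube()
        base = SensorSpec(k_sensor=10.0, force_noise_sd_nN=0.0, capillary_slope=0.0)
        withc = SensorSpec(k_sensor=10.0, force_noise_sd_nN=0.0,
                           capillary_slope=0.01 * tube.k_load_true)
        k0 = process_curve(
            synthesize_curve(tube, base, protocol, 1.5, beta=0.1, seed=0)
        )["k_load_N_per_m"]
        k1 = process_curve(
            synthesize_curve(tube, withc, protocol, 1.5, beta=0.1, seed=0)
        )["k_load_N_per_m"]
        assert abs(k1 - k0) / k0 < 0.02


class TestCohortStatistics:
    def test_simple_arithmetic(self):
        df = pd.DataFrame(
            {
                "tube_id": ["a", "b", "c"],
                "group": ["g"] * 3,
                "k_load_N_per_m": [1.0, 2.0, 3.0],
                "k_unload_N_per_m": [2.0, 3.0, 4.0],
            }
        )
        st = cohort_statistics(df, "g")
        assert st.load_mean == pytest.approx(2.0)
        assert st.load_median == pytest.approx(2.0)
        assert st.unload_mean == pytest.approx(3.0)
        assert st.n_tubes == 3 and st.m_indentations == 3

    def test_pooling_is_per_indentation(self):
        """A tube with many indentations weighs more than a tube with one."""
        df = pd.DataFrame(
            {
                "tube_id": ["a"] * 3 + ["b"],
                "group": ["g"] * 4,
                "k_load_N_per_m": [1.0, 1.0, 1.0, 5.0],
                "k_unload_N_per_m": [1.0, 1.0, 1.0, 5.0],
            }
        )
        st = cohort_statistics(df, "g")
        assert st.load_mean == pytest.approx(2.0)  # not the tube-mean 3.0

    def test_single_record_rejected(self):
        df = pd.DataFrame(
            {"tube_id": ["a"], "group": ["g"], "k_load_N_per_m": [1.0],
             "k_unload_N_per_m": [1.0]}
        )
        with pytest.raises(ValueError):
            cohort_statistics(df, "g")
        with pytest.raises(ValueError):
            cohort_statistics(df, "missing")

    def test_pipeline_recovers_generator_truth_unbiased(self, lily):
        """Pooled measured statistics track the cohorts' own pooled truth
        to < 2% per phase (estimator bias, separated from sampling noise)."""
        devs_l, devs_u = [], []
        for seed in spawn_seeds(55, 10):
            curves, manifest = simulate_cohort(lily, "growing", seed=seed)
            records = process_cohort(curves)
            truth = {t["id"]: t for t in manifest["tubes"]}
            merged = records.assign(
                kl_true=[truth[t]["k_load_true_N_per_m"] for t in records["tube_id"]],
                ku_true=[truth[t]["k_unload_true_N_per_m"] for t in records["tube_id"]],
            )
            devs_l.append(
                merged["k_load_N_per_m"].mean() / merged["kl_true"].mean() - 1
            )
            devs_u.append(
                merged["k_unload_N_per_m"].mean() / merged["ku_true"].mean() - 1
            )
        assert abs(np.mean(devs_l)) < 0.02
        assert abs(np.mean(devs_u)) < 0.02


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a.copy(), n_perm=999, seed=0)
        assert res["difference_of_means"] == 0.0
        assert res["p_value"] == pytest.approx(1.0, abs=0.01)

    def test_tiny_case_matches_exhaustive_enumeration(self):
        a, b = np.array([10.0, 11.0]), np.array([1.0, 2.0])
        obs = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        count = sum(
            1
            for idx in itertools.combinations(range(4), 2)
            if abs(
                pooled[list(idx)].mean()
                - pooled[[i for i in range(4) if i not in idx]].mean()
            )
            >= abs(obs) - 1e-12
        )
        p_exact = count / 6.0
        res = compare_groups(a, b, n_perm=9999, seed=1)
        assert res["p_value"] == pytest.approx(p_exact, abs=0.03)

    def test_growing_vs_nongrowing_significant(self, lily):
        """Power at the printed cohort sizes: the growing/non-growing
        stiffness separation is detected in every seeded replicate."""
        for seed in spawn_seeds(77, 5):
            ga, _ = simulate_cohort(lily, "growing", seed=seed)
            gb, _ = simulate_cohort(lily, "non_growing", seed=seed + 1)
            ra, rb = process_cohort(ga), process_cohort(gb)
            res = compare_groups(
                ra["k_load_N_per_m"].to_numpy(),
                rb["k_load_N_per_m"].to_numpy(),
                n_perm=999,
                seed=seed,
            )
            assert res["p_value"] < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([]), np.array([1.0]))


class TestApexProfile:
    def test_attenuation_gradient_detected(self, lily):
        curves, _ = simulate_cohort(lily, "growing", n_tubes=19, m_indent=135,
                                    distance_mode="apex", seed=13)
        records = process_cohort(curves)
        table, trend = apex_profile(records, bin_width=1.0)
        assert trend["spearman_rho"] > 0.5
        assert trend["p_value"] < 0.05
        assert np.all(np.diff(table["distance_um"]) > 0)

    def test_no_gradient_without_attenuation(self, lily):
        curves, _ = simulate_cohort(lily, "growing", n_tubes=19, m_indent=135,
                                    distance_mode="apex", seed=13,
                                    attenuation=False)
        records = process_cohort(curves)
        _, trend = apex_profile(records, bin_width=1.0)
        assert trend["p_value"] > 0.05

    def test_single_bin_rejected(self):
        df = pd.DataFrame(
            {
                "distance_from_tip_um": [50.1, 50.2, 50.3],
                "k_unload_N_per_m": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            apex_profile(df, bin_width=5.0)
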