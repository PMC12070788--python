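"""Generative-structure tests for the synthetic cohort simulator."""

import numpy as np
import pytest
from scipy import stats

import ehrjoint as ej
from ehrjoint.simulator import (
    evaluate_trajectory,
    simulate_cohort,
    simulate_covariates,
    simulate_event_time,
    simulate_measurement_times,
    simulate_n_measurements,
)


def floor_abs_normal_mean(mu, sd, upper=400):
    """Closed-form E[floor(|X|)] for X ~ N(mu, sd^2): oracle by summation.

    floor(|X|) >= k+1  iff  |X| >= k+1, so the mean is sum_k P(|X| > k+1).
    """
    ks = np.arange(0, upper)
    p_above = stats.norm.sf(ks + 1, mu, sd) + stats.norm.cdf(-(ks + 1), mu, sd)
    return float(np.sum(p_above))


class TestEventTime:
    def test_control_censored_at_horizon(self, rng):
        assert simulate_event_time(False, rng) == 120.0

    def test_case_support_and_uniformity(self):
        rng = np.random.default_rng(0)
        draws = np.array([simulate_event_time(True, rng) for _ in range(10_000)])
        assert draws.min() >= 10 and draws.max() < 120
        # GOF against Uniform(10, 120)
        stat, p = stats.kstest(draws, stats.uniform(10, 110).cdf)
        assert p > 0.01

    def test_seeded_determinism(self):
        a = simulate_event_time(True, np.random.default_rng(5))
        b = simulate_event_time(True, np.random.default_rng(5))
        assert a == b


class TestMeasurementCount:
    def test_mean_matches_floor_normal_oracle(self):
        rng = np.random.default_rng(1)
        draws = [simulate_n_measurements(2.0, 120.0, rng) for _ in range(100_000)]
        expected = floor_abs_normal_mean(20.0, 2.0)
        assert expected == pytest.approx(19.5, abs=0.01)  # abs-part negligible
        assert np.mean(draws) == pytest.approx(expected, abs=0.05)

    def test_zero_rate_folded_normal_oracle(self):
        rng = np.random.default_rng(2)
        draws = [simulate_n_measurements(0.0, 120.0, rng) for _ in range(100_000)]
        expected = floor_abs_normal_mean(0.0, 2.0)
        assert np.mean(draws) == pytest.approx(expected, abs=0.05)
        assert min(draws) >= 0


class TestMeasurementTimes:
    def test_zero_count_empty(self, rng):
        assert len(simulate_measurement_times(0, 75, 60, rng)) == 0

    def test_within_window_for_late_event(self, rng):
        times = simulate_measurement_times(12, 75.0, 60, rng)
        assert len(times) == 12
        assert times.min() >= 0 and times.max() <= 60
        assert (np.diff(times) >= 0).all()

    def test_uniform_over_support(self):
        rng = np.random.default_rng(3)
        draws = np.concatenate(
            [simulate_measurement_times(100, 40.0, 60, rng) for _ in range(1000)]
        )
        counts = np.bincount(draws, minlength=41)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_literal_mode_drops_out_of_window(self):
        rng = np.random.default_rng(4)
        times = simulate_measurement_times(1000, 119.0, 60, rng, literal=True)
        assert times.max() <= 60
        assert len(times) < 1000  # some draws landed past the window


class TestTrajectory:
    def test_control_params(self):
        rng = np.random.default_rng(6)
        cfg = ej.REFERENCE_CONFIG
        resp, b, m = ej.assign_trajectory_params(False, cfg, rng)
        assert resp is False and m == 0.0
        bs = [ej.assign_trajectory_params(False, cfg, rng)[1] for _ in range(10_000)]
        assert np.mean(bs) == pytest.approx(0.5, abs=3 * cfg.intercept_sd / 100 * 10)

    def test_degenerate_slope(self):
        rng = np.random.default_rng(7)
        cfg = ej.REFERENCE_CONFIG.replace(responder_fraction=1.0, slope_sd=0.0)
        _, _, m = ej.assign_trajectory_params(True, cfg, rng)
        assert m == cfg.slope_mean

    def test_case_intercept_shift(self):
        rng = np.random.default_rng(8)
        cfg = ej.REFERENCE_CONFIG
        bs = [ej.assign_trajectory_params(True, cfg, rng)[1] for _ in range(10_000)]
        assert np.mean(bs) == pytest.approx(0.6, abs=3 * cfg.intercept_sd / 100)

    def test_hinge_shape(self):
        cfg = ej.REFERENCE_CONFIG.replace(slope_years=5.0)
        # event at 75, breakpoint at 75 - 60 = 15
        assert evaluate_trajectory(10.0, 0.3, 0.005, 75.0, cfg) == pytest.approx(0.3)
        assert evaluate_trajectory(75.0, 0.3, 0.005, 75.0, cfg) == pytest.approx(
            0.3 + 0.005 * 60
        )

    def test_flat_when_no_slope(self):
        cfg = ej.REFERENCE_CONFIG
        assert evaluate_trajectory(37.0, 0.5, 0.0, 120.0, cfg) == 0.5

    def test_nondecreasing_for_positive_slope(self):
        cfg = ej.REFERENCE_CONFIG
        t = np.linspace(0, 75, 100)
        y = evaluate_trajectory(t, 0.4, 0.007, 75.0, cfg)
        assert (np.diff(y) >= 0).all()

    def test_literal_breakpoint_gates_slope_early(self):
        cfg = ej.REFERENCE_CONFIG.replace(literal_breakpoint=True)
        # slope applies only while t <= breakpoint (printed variant)
        y_pre = evaluate_trajectory(10.0, 0.3, 0.005, 75.0, cfg)
        y_post = evaluate_trajectory(60.0, 0.3, 0.005, 75.0, cfg)
        assert y_pre == pytest.approx(0.3 + 0.05)
        assert y_post == pytest.approx(0.3)


class TestCovariates:
    def test_supports(self):
        rng = np.random.default_rng(9)
        for is_case in (True, False):
            for _ in range(200):
                sex, age, smoking = simulate_covariates(is_case, rng)
                assert sex in (0, 1) and smoking in (0, 1)
                assert 30 <= age <= 90

    def test_case_control_age_gap(self):
        rng = np.random.default_rng(10)
        a_case = [simulate_covariates(True, rng)[1] for _ in range(10_000)]
        a_ctrl = [simulate_covariates(False, rng)[1] for _ in range(10_000)]
        assert np.mean(a_case) - np.mean(a_ctrl) == pytest.approx(5.0, abs=0.3)


class TestCohort:
    def test_balanced_design(self, reference_cohort):
        subj = reference_cohort.subjects
        assert subj.is_case.sum() == 250
        assert (~subj.is_case).sum() == 250
        # case/control invariants
        ctrl = subj[~subj.is_case]
        assert (ctrl.event_time == 120).all() and (~ctrl.event_observed).all()
        assert (~ctrl.responder).all() and (ctrl.slope == 0).all()
        cases = subj[subj.is_case]
        assert cases.event_time.between(10, 120, inclusive="left").all()
        assert cases.event_observed.all()

    def test_observation_invariants(self, reference_cohort):
        df = reference_cohort.observations.merge(
            reference_cohort.subjects[["subject_id", "event_time"]], on="subject_id"
        )
        assert (df.time <= 60).all()
        assert (df.time <= df.event_time).all()

    def test_seed_reproducibility(self):
        cfg = ej.REFERENCE_CONFIG.replace(n_subjects=80, seed=99)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.subjects.equals(b.subjects)
        assert a.observations.equals(b.observations)

    def test_zero_noise_matches_trajectory(self):
        cfg = ej.REFERENCE_CONFIG.replace(n_subjects=50, noise_sd=0.0, seed=3)
        c = simulate_cohort(cfg)
        df = c.observations.merge(c.subjects, on="subject_id")
        expected = [
            evaluate_trajectory(r.time, r.intercept, r.slope, r.event_time, cfg)
            for r in df.itertuples()
        ]
        np.testing.assert_allclose(df.value.to_numpy(), expected, atol=1e-12)

    def test_values_not_clipped(self, reference_cohort):
        v = reference_cohort.observations.value
        assert ((v < 0) | (v > 1)).mean() > 0

    def test_null_scenario_groups_indistinguishable(self):
        cfg = ej.REFERENCE_CONFIG.replace(
            n_subjects=2000, responder_fraction=0.0, intercept_shift=0.0, seed=17
        )
        c = simulate_cohort(cfg)
        df = c.observations.merge(c.subjects[["subject_id", "is_case"]], on="subject_id")
        _, p = stats.ks_2samp(df[df.is_case].value, df[~df.is_case].value)
        assert p > 0.01

    def test_case_measurement_count_matches_floor_correction(self):
        # with event time ~e, count ~ floor(|N(2e/12, 2)|), mean ~ 2e/12 - 0.5
        cfg = ej.REFERENCE_CONFIG.replace(n_subjects=3000, seed=21)
        c = simulate_cohort(cfg)
        cases = c.subjects[c.subjects.is_case]
        counts = (
            c.observations.groupby("subject_id")
            .size()
            .reindex(cases.subject_id)
            .fillna(0)
        )
        expected = (2 * cases.event_time.mean() / 12) - 0.5
        assert counts.mean() == pytest.approx(expected, abs=0.15)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_subjects", 0),
            ("noise_sd", -0.1),
            ("responder_fraction", 1.2),
            ("intercept_shift", 0.7),
            ("obs_end", 130),
            ("slope_years", 0.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ej.ConfigError, match=field):
            ej.REFERENCE_CONFIG.replace(**{field: value})

    def test_defaults_reproduce_reference_setting(self):
        cfg = ej.ScenarioConfig()
        assert (cfg.n_subjects, cfg.noise_sd, cfg.responder_fraction) == (500, 0.15, 1.0)
        assert (cfg.slope_years, cfg.measurements_per_year) == (3.0, 2.0)
        assert (cfg.intercept_shift, cfg.intercept_sd) == (0.1, 0.05)
        assert (cfg.slope_mean, cfg.slope_sd) == (0.005, 0.005)
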