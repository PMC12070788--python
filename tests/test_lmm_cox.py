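"""Tests for the mixed-model and Cox candidate models."""

import numpy as np
import pandas as pd
import pytest

import ehrjoint as ej
from ehrjoint.cox import extract_last_value


def _toy_long(n_subj=8, n_obs=6, slope=0.01, intercept=0.4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(n_subj):
        times = np.sort(rng.integers(0, 61, n_obs))
        vals = intercept + slope * times + rng.normal(0, noise, n_obs)
        for t, v in zip(times, vals):
            rows.append((sid, t, v))
    obs = pd.DataFrame(rows, columns=["subject_id", "time", "value"])
    cov = pd.DataFrame(
        {
            "subject_id": range(n_subj),
            "sex": rng.integers(0, 2, n_subj),
            "age": rng.normal(60, 8, n_subj),
            "smoking": rng.integers(0, 2, n_subj),
        }
    )
    return obs, cov


class TestLMM:
    def test_zero_noise_common_line(self):
        obs, cov = _toy_long(noise=0.0)
        fit = ej.fit_lmm(obs, cov)
        assert fit.resid_sd < 1e-3
        assert fit.fixed_effects["time"] == pytest.approx(0.01, abs=1e-5)
        assert np.all(np.abs(fit.ranef_cov) < 1e-4)

    def test_noise_recovery_reference_cohort(self, reference_cohort, reference_subjects):
        fit = ej.fit_lmm(reference_cohort.observations, reference_subjects)
        assert fit.resid_sd == pytest.approx(0.15, rel=0.10)

    def test_eb_ranefs_track_subject_truth(self):
        # one subject with many dense low-noise points far from the others
        rng = np.random.default_rng(1)
        obs, cov = _toy_long(n_subj=30, n_obs=8, noise=0.02, seed=2)
        times = np.arange(0, 60)
        special = pd.DataFrame(
            {"subject_id": 99, "time": times,
             "value": 0.8 + 0.02 * times + rng.normal(0, 0.02, len(times))}
        )
        obs = pd.concat([obs, special], ignore_index=True)
        cov = pd.concat(
            [cov, pd.DataFrame({"subject_id": [99], "sex": [0], "age": [60.0],
                                "smoking": [0]})],
            ignore_index=True,
        )
        fit = ej.fit_lmm(obs, cov)
        # EB mode + fixed effects should reproduce the subject's own line
        x0 = fit.fixed_effects["const"] + fit.fixed_effects["age"] * 60.0
        ols = np.polyfit(times, special["value"], 1)
        assert x0 + fit.subject_ranefs.loc[99, "b0"] == pytest.approx(ols[1], abs=0.05)
        assert fit.fixed_effects["time"] + fit.subject_ranefs.loc[99, "b1"] == (
            pytest.approx(ols[0], abs=0.005)
        )

    def test_singular_design_names_column(self):
        obs, cov = _toy_long()
        cov["smoking"] = cov["sex"]  # perfectly collinear
        with pytest.raises(ValueError, match="smoking"):
            ej.fit_lmm(obs, cov)

    def test_empty_observations_error(self):
        obs, cov = _toy_long()
        with pytest.raises(ValueError, match="no longitudinal"):
            ej.fit_lmm(obs.iloc[:0], cov)


def breslow_partial_loglik(beta, times, events, x):
    """Printed Cox partial log-likelihood with Breslow ties (oracle)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestCox:
    def test_toy_coefficient_matches_grid_oracle(self):
        times = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        events = np.array([1, 1, 0, 1, 1, 0], dtype=bool)
        x = np.array([0.2, 0.9, 0.1, 0.5, 0.8, 0.3])
        grid = np.linspace(-5, 5, 20001)
        lls = [breslow_partial_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        surv = pd.DataFrame(
            {"subject_id": range(6), "event_time": times, "event_observed": events}
        )
        cov = pd.DataFrame({"subject_id": range(6), "marker": x})
        fit = ej.fit_cox(surv, cov, feature_cols=("marker",))
        assert fit.coefficients["marker"] == pytest.approx(beta_star, abs=1e-3)

    def test_constant_covariate_coefficient_zero(self):
        rng = np.random.default_rng(3)
        surv = pd.DataFrame(
            {"subject_id": range(40), "event_time": rng.uniform(10, 100, 40),
             "event_observed": rng.random(40) < 0.7}
        )
        cov = pd.DataFrame(
            {"subject_id": range(40), "flat": 1.0, "x": rng.normal(size=40)}
        )
        fit = ej.fit_cox(surv, cov, feature_cols=("flat", "x"))
        assert fit.coefficients["flat"] == 0.0
        assert "flat" in fit.dropped_constant

    def test_no_events_error(self):
        surv = pd.DataFrame(
            {"subject_id": [0, 1], "event_time": [120.0, 120.0],
             "event_observed": [False, False]}
        )
        cov = pd.DataFrame({"subject_id": [0, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            ej.fit_cox(surv, cov, feature_cols=("x",))

    def test_last_value_coefficient_positive_on_responder_cohort(
        self, reference_cohort, reference_subjects
    ):
        surv = reference_cohort.survival_table()
        last = ej.impute_last_values(
            extract_last_value(reference_cohort.observations, 60,
                               subject_ids=surv.subject_id)
        )
        cov = reference_cohort.covariate_table().merge(
            last.reset_index(), on="subject_id"
        )
        fit = ej.fit_cox(surv, cov, feature_cols=("sex", "age", "smoking", "last_value"))
        assert fit.coefficients["last_value"] > 0


class TestLastValue:
    def test_takes_latest_in_window(self):
        obs = pd.DataFrame(
            {"subject_id": [1, 1, 1], "time": [3, 14, 59], "value": [0.1, 0.2, 0.3]}
        )
        assert extract_last_value(obs, 60)[1] == 0.3

    def test_ignores_out_of_window(self):
        obs = pd.DataFrame(
            {"subject_id": [1, 1], "time": [10, 70], "value": [0.1, 0.9]}
        )
        assert extract_last_value(obs, 60)[1] == 0.1

    def test_missing_subject_nan(self):
        obs = pd.DataFrame({"subject_id": [1], "time": [5], "value": [0.4]})
        out = extract_last_value(obs, 60, subject_ids=[1, 2])
        assert np.isnan(out[2])

    def test_tied_last_time_averaged(self):
        obs = pd.DataFrame(
            {"subject_id": [1, 1], "time": [59, 59], "value": [0.2, 0.4]}
        )
        assert extract_last_value(obs, 60)[1] == pytest.approx(0.3)

    def test_imputation_warns_and_fills_mean(self):
        last = pd.Series([0.2, np.nan, 0.4], index=pd.Index([1, 2, 3], name="subject_id"))
        with pytest.warns(UserWarning, match="imputing"):
            filled = ej.impute_last_values(last)
        assert filled[2] == pytest.approx(0.3)


class TestCoxRisk:
    def test_zero_coefficients_give_identical_risks(self):
        rng = np.random.default_rng(4)
        n = 30
        surv = pd.DataFrame(
            {"subject_id": range(n), "event_time": rng.uniform(61, 120, n),
             "event_observed": rng.random(n) < 0.5}
        )
        cov = pd.DataFrame({"subject_id": range(n), "x": rng.normal(size=n)})
        fit = ej.fit_cox(surv, cov, feature_cols=("x",))
        fit.coefficients["x"] = 0.0
        fit.model.params_["x"] = 0.0
        risks = ej.predict_risk_cox(fit, cov, np.arange(60, 121), 60)
        assert np.allclose(risks.risks, risks.risks[0][None, :])

    def test_risk_zero_at_obs_end_and_monotone(self, reference_cohort, reference_subjects):
        surv = reference_cohort.survival_table()
        cov = reference_cohort.covariate_table()
        fit = ej.fit_cox(surv, cov)
        at = ej.filter_at_risk(surv, 60)
        cov_at = cov[cov.subject_id.isin(at.subject_id)]
        risks = ej.predict_risk_cox(fit, cov_at, np.arange(60, 121), 60)
        risks.validate()

    def test_conditional_risk_matches_mc_oracle(self):
        """r_i(t) agrees with Monte-Carlo simulation from the fitted hazard."""
        rng = np.random.default_rng(5)
        n = 200
        x = rng.normal(size=n)
        base_t = rng.exponential(80, n) * np.exp(-0.5 * x)
        surv = pd.DataFrame(
            {"subject_id": range(n), "event_time": np.clip(base_t, 1, 120),
             "event_observed": base_t < 120}
        )
        cov = pd.DataFrame({"subject_id": range(n), "x": x})
        fit = ej.fit_cox(surv, cov, feature_cols=("x",))
        sub = cov.iloc[[0]]
        risks = ej.predict_risk_cox(fit, sub, np.array([60, 90, 120]), 60)

        # MC oracle: invert the subject's predicted cumulative hazard
        H = fit.model.predict_cumulative_hazard(
            sub.set_index("subject_id"), times=np.linspace(0, 120, 2000)
        )
        tgrid = H.index.to_numpy()
        Hvals = H.iloc[:, 0].to_numpy()
        e = rng.exponential(1.0, 100_000)
        T = np.interp(e, Hvals, tgrid, right=np.inf)
        alive60 = T > 60
        for j, t in enumerate([60, 90, 120]):
            mc = np.mean(T[alive60] <= t)
            assert risks.risks[0, j] == pytest.approx(mc, abs=0.01)
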