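"""Synthetic longitudinal primary-care cohort generator.

Generates cohorts with the full generative structure used by the
simulation study:

* a balanced case/control design; cases receive a diagnosis time drawn
  uniformly on [10, 120) months, controls are administratively censored
  at the 120-month horizon;
* per-subject measurement counts ``floor(|N(n_abs * t_event / 12, 2)|)``;
* integer measurement dates uniform over the in-window months;
* piecewise-linear biomarker trajectories: flat at a subject-specific
  intercept until a breakpoint ``t_event - 12 * slope_years`` months,
  rising linearly thereafter for "responder" cases (Bernoulli responder
  mechanism), with a between-group intercept shift;
* i.i.d. Gaussian measurement noise (values are NOT clipped to [0, 1]:
  clipping would bias noise-recovery downstream);
* baseline covariates (sex, age, smoking) whose distributions differ
  between cases and controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, ScenarioConfig

SUBJECT_COLUMNS = [
    "subject_id",
    "is_case",
    "event_time",
    "event_observed",
    "sex",
    "age",
    "smoking",
    "responder",
    "intercept",
    "slope",
]
OBSERVATION_COLUMNS = ["subject_id", "time", "value"]
#: latent generative truth, written to disk only on request
TRUTH_COLUMNS = ["is_case", "responder", "intercept", "slope"]
COVARIATE_COLUMNS = ["sex", "age", "smoking"]


@dataclass
class Cohort:
    """A simulated cohort: per-subject table plus long-format observations."""

    config: ScenarioConfig
    subjects: pd.DataFrame
    observations: pd.DataFrame

    def survival_table(self) -> pd.DataFrame:
        return self.subjects[["subject_id", "event_time", "event_observed"]].copy()

    def covariate_table(self) -> pd.DataFrame:
        return self.subjects[["subject_id", *COVARIATE_COLUMNS]].copy()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def simulate_event_time(is_case: bool, rng: np.random.Generator, horizon: float = 120.0) -> float:
    """Diagnosis time in months: Uniform(10, horizon) for cases, horizon for controls."""
    if not is_case:
        return float(horizon)
    return float(rng.uniform(10.0, horizon))


def simulate_n_measurements(
    measurements_per_year: float, event_time: float, rng: np.random.Generator
) -> int:
    """Number of biomarker measurements for a subject followed to ``event_time``.

    Drawn as ``floor(|N(n_abs * event_time / 12, sd=2)|)``; the absolute
    value keeps the count nonnegative for low measurement frequencies.
    """
    if event_time <= 0:
        raise ValueError(f"event_time must be positive, got {event_time}")
    draw = rng.normal(measurements_per_year * event_time / 12.0, 2.0)
    return int(math.floor(abs(draw)))


def simulate_measurement_times(
    n: int,
    event_time: float,
    obs_end: float,
    rng: np.random.Generator,
    literal: bool = False,
) -> np.ndarray:
    """``n`` integer measurement months, sorted ascending.

    Default: uniform on {0, ..., min(event_time, obs_end)} so all sampled
    dates fall in the observation window.  ``literal=True`` draws on
    {0, ..., event_time} and then drops out-of-window dates (audit mode).
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    if n == 0:
        return np.empty(0, dtype=int)
    if literal:
        hi = int(math.floor(event_time))
        times = rng.integers(0, hi + 1, size=n)
        times = times[times <= obs_end]
    else:
        hi = int(math.floor(min(event_time, obs_end)))
        times = rng.integers(0, hi + 1, size=n)
    return np.sort(times)


def assign_trajectory_params(
    is_case: bool, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[bool, float, float]:
    """Draw (responder, intercept, slope) for one subject.

    Cases respond with probability ``responder_fraction``; responders get a
    Gaussian slope (per month), everyone else slope 0.  Case intercepts are
    shifted up by ``intercept_shift`` relative to the control mean of 0.5.
    """
    responder = bool(is_case and rng.random() < config.responder_fraction)
    slope = float(rng.normal(config.slope_mean, config.slope_sd)) if responder else 0.0
    mean_b = 0.5 + (config.intercept_shift if is_case else 0.0)
    intercept = float(rng.normal(mean_b, config.intercept_sd))
    return responder, intercept, slope


def trajectory_breakpoint(event_time: float, slope_years: float) -> float:
    """Month at which a case's trajectory departs from its flat baseline."""
    return event_time - 12.0 * slope_years


def evaluate_trajectory(
    time: np.ndarray | float,
    intercept: float,
    slope: float,
    event_time: float,
    config: ScenarioConfig,
) -> np.ndarray | float:
    """Noiseless biomarker value(s) at ``time`` months.

    Flat at ``intercept`` until the breakpoint, then rising with ``slope``
    (hinge form, continuous at the breakpoint).  The ``literal_breakpoint``
    switch instead applies the slope to t only while t is at or before the
    breakpoint (discontinuous audit variant).
    """
    t = np.asarray(time, dtype=float)
    t_break = trajectory_breakpoint(event_time, config.slope_years)
    if config.literal_breakpoint:
        out = intercept + slope * t * (t <= t_break)
    else:
        out = intercept + slope * np.maximum(0.0, t - t_break)
    if np.isscalar(time):
        return float(out)
    return out


def simulate_covariates(
    is_case: bool, rng: np.random.Generator, spec=None
) -> tuple[int, float, int]:
    """Draw (sex, age, smoking) for one subject.

    Age is Gaussian truncated to [age_min, age_max] by resampling.
    """
    from .config import CovariateSpec

    spec = spec or CovariateSpec()
    p_sex = spec.sex_prob_case if is_case else spec.sex_prob_control
    sex = int(rng.random() < p_sex)
    mu = spec.age_mean_case if is_case else spec.age_mean_control
    age = rng.normal(mu, spec.age_sd)
    while not (spec.age_min <= age <= spec.age_max):
        age = rng.normal(mu, spec.age_sd)
    p_smoke = spec.smoking_prob_case if is_case else spec.smoking_prob_control
    smoking = int(rng.random() < p_smoke)
    return sex, float(age), smoking


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate a full cohort, bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cases = math.ceil(config.n_subjects * config.case_fraction)

    subj_rows = []
    obs_frames = []
    for sid in range(config.n_subjects):
        is_case = sid < n_cases
        event_time = simulate_event_time(is_case, rng, config.horizon)
        event_observed = bool(is_case)
        sex, age, smoking = simulate_covariates(is_case, rng, config.covariates)
        responder, intercept, slope = assign_trajectory_params(is_case, config, rng)
        n_meas = simulate_n_measurements(config.measurements_per_year, event_time, rng)
        times = simulate_measurement_times(
            n_meas, event_time, config.obs_end, rng, literal=config.literal_measurement_times
        )
        subj_rows.append(
            (sid, is_case, event_time, event_observed, sex, age, smoking,
             responder, intercept, slope)
        )
        if len(times):
            mean_vals = evaluate_trajectory(times, intercept, slope, event_time, config)
            values = mean_vals + rng.normal(0.0, config.noise_sd, size=len(times))
            obs_frames.append(
                pd.DataFrame({"subject_id": sid, "time": times, "value": values})
            )

    subjects = pd.DataFrame(subj_rows, columns=SUBJECT_COLUMNS)
    if obs_frames:
        observations = pd.concat(obs_frames, ignore_index=True)
    else:
        observations = pd.DataFrame(
            {"subject_id": pd.Series(dtype=int),
             "time": pd.Series(dtype=int),
             "value": pd.Series(dtype=float)}
        )
    return Cohort(config=config, subjects=subjects, observations=observations)
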