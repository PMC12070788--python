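import numpy as np
import pandas as pd
import pytest

import ehrjoint as ej


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small reference-setting cohort reused by model tests."""
    return ej.simulate_cohort(ej.REFERENCE_CONFIG.replace(n_subjects=150, seed=42))


@pytest.fixture(scope="session")
def small_subjects(small_cohort):
    return small_cohort.survival_table().merge(
        small_cohort.covariate_table(), on="subject_id"
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """A full-size reference cohort (N=500)."""
    return ej.simulate_cohort(ej.REFERENCE_CONFIG.replace(seed=7))


@pytest.fixture(scope="session")
def reference_subjects(reference_cohort):
    return reference_cohort.survival_table().merge(
        reference_cohort.covariate_table(), on="subject_id"
    )


def random_risks_and_survival(rng, n, horizon=120):
    """Random risk matrix + survival table for tvC tests."""
    ids = np.arange(n)
    is_event = rng.random(n) < 0.6
    times = np.where(is_event, rng.uniform(10, horizon, n), horizon)
    surv = pd.DataFrame(
        {"subject_id": ids, "event_time": times, "event_observed": is_event}
    )
    eval_times = np.arange(60, horizon + 1)
    base = rng.random((n, 1))
    incr = np.cumsum(rng.random((n, len(eval_times))) * 0.01, axis=1)
    risks = np.concatenate([np.zeros((n, 1)), base * incr[:, 1:]], axis=1)
    return ej.RiskMatrix(ids, eval_times, risks), surv
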