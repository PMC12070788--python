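"""Cox proportional-hazards candidate models.

Two Cox variants are compared against the joint model: a baseline model
using only fixed covariates, and a "last value" model that additionally
includes the most recent in-window biomarker measurement.  Fitting uses
lifelines' partial-likelihood maximizer with Breslow tie handling and
Breslow baseline hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .risk import RiskMatrix


@dataclass
class CoxFit:
    coefficients: pd.Series
    baseline_cumhaz: pd.Series  # step function over months, 0 at time 0
    loglik: float
    converged: bool = True
    model: CoxPHFitter | None = None
    dropped_constant: tuple = field(default_factory=tuple)
    feature_cols: tuple = field(default_factory=tuple)


def extract_last_value(
    observations: pd.DataFrame, obs_end: float, subject_ids=None
) -> pd.Series:
    """Most recent in-window biomarker value per subject.

    Values tied at the last time are averaged; subjects without any
    in-window observation get NaN.  If ``subject_ids`` is given the result
    is reindexed to it (missing subjects -> NaN).
    """
    inwin = observations[observations["time"] <= obs_end]
    if len(inwin) == 0:
        last = pd.Series(dtype=float, name="last_value")
    else:
        tmax = inwin.groupby("subject_id")["time"].transform("max")
        at_last = inwin[inwin["time"] == tmax]
        last = at_last.groupby("subject_id")["value"].mean().rename("last_value")
    if subject_ids is not None:
        last = last.reindex(pd.Index(subject_ids, name="subject_id"))
    return last


def impute_last_values(last: pd.Series) -> pd.Series:
    """Fill missing last values with the cohort mean (with a warning)."""
    if last.isna().any():
        if last.notna().sum() == 0:
            raise ValueError("no subject has an in-window biomarker value")
        warnings.warn(
            f"imputing {int(last.isna().sum())} missing last biomarker values "
            "with the cohort mean",
            stacklevel=2,
        )
        last = last.fillna(last.mean())
    return last


def fit_cox(
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    feature_cols=("sex", "age", "smoking"),
) -> CoxFit:
    """Fit a Cox model by partial likelihood (Breslow ties and baseline).

    ``covariates`` may include a ``last_value`` column for the biomarker
    variant.  Constant columns are dropped and reported with coefficient 0
    (a flat partial-likelihood profile).  Raises ``ValueError`` when no
    event is observed.
    """
    feature_cols = tuple(feature_cols)
    if survival["event_observed"].astype(bool).sum() == 0:
        raise ValueError("cannot fit a Cox model without any observed event")
    df = survival.merge(covariates, on="subject_id", validate="1:1")
    data = df[["event_time", "event_observed", *feature_cols]].astype(float)

    dropped = tuple(c for c in feature_cols if data[c].nunique() <= 1)
    used = [c for c in feature_cols if c not in dropped]

    cph = CoxPHFitter(baseline_estimation_method="breslow")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                data[["event_time", "event_observed", *used]],
                duration_col="event_time",
                event_col="event_observed",
            )
    except ConvergenceError as err:
        flagged = CoxFit(
            coefficients=pd.Series(0.0, index=list(feature_cols)),
            baseline_cumhaz=pd.Series(dtype=float),
            loglik=float("nan"),
            converged=False,
            model=None,
            dropped_constant=dropped,
            feature_cols=feature_cols,
        )
        flagged.coefficients.attrs["error"] = str(err)
        return flagged

    coefs = pd.Series(0.0, index=list(feature_cols))
    coefs[used] = cph.params_.values
    ch = cph.baseline_cumulative_hazard_.iloc[:, 0]
    return CoxFit(
        coefficients=coefs,
        baseline_cumhaz=ch,
        loglik=float(cph.log_likelihood_),
        converged=converged,
        model=cph,
        dropped_constant=dropped,
        feature_cols=feature_cols,
    )


def predict_risk_cox(
    fit: CoxFit,
    covariates: pd.DataFrame,
    eval_times: np.ndarray,
    obs_end: float,
) -> RiskMatrix:
    """Conditional cumulative risk given event-free status at ``obs_end``.

    r_i(t) = 1 - exp(-(H_i(t) - H_i(obs_end))) with H_i the subject's
    predicted cumulative hazard.
    """
    if fit.model is None:
        raise ValueError("cannot predict from a non-converged Cox fit")
    eval_times = np.asarray(eval_times, dtype=int)
    used = [c for c in fit.feature_cols if c not in fit.dropped_constant]
    X = covariates.set_index("subject_id")[used].astype(float)
    times = np.unique(np.concatenate([[obs_end], eval_times]).astype(float))
    H = fit.model.predict_cumulative_hazard(X, times=times)  # times x subjects
    H0 = H.loc[float(obs_end)].to_numpy()
    Ht = H.loc[eval_times.astype(float)].to_numpy().T  # subjects x times
    risks = 1.0 - np.exp(-(Ht - H0[:, None]))
    risks = np.maximum(risks, 0.0)
    return RiskMatrix(X.index.to_numpy(), eval_times, risks)
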