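"""Linear mixed-effects working model for the longitudinal biomarker.

The candidate-model formulation is linear in time (no breakpoint), with
fixed effects for intercept, time and baseline covariates, and a random
intercept + random slope per subject.  Fitting is delegated to
statsmodels' MixedLM (maximum likelihood by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

RESID_SD_FLOOR = 1e-6


@dataclass
class LMMFit:
    """Parameter bundle of a fitted linear mixed model.

    ``fixed_effects`` is indexed intercept, time, then covariates;
    ``ranef_cov`` is the 2x2 covariance of (random intercept, random slope);
    ``subject_ranefs`` holds the empirical-Bayes modes per subject.
    """

    fixed_effects: pd.Series
    ranef_cov: np.ndarray
    resid_sd: float
    subject_ranefs: pd.DataFrame
    loglik: float
    converged: bool = True
    covariate_cols: tuple = field(default_factory=tuple)

    def __post_init__(self):
        D = np.asarray(self.ranef_cov, dtype=float)
        if D.shape != (2, 2) or not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("ranef_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(D)) < -1e-8:
            raise ValueError("ranef_cov must be positive semidefinite")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")


#: time is rescaled to years inside the optimizer: the per-month random
#: slope variance is ~1e-5 on normalized data, which conditions the
#: variance-component search badly in month units
_TIME_SCALE = 12.0


def _design(observations, covariates, covariate_cols):
    df = observations.merge(covariates, on="subject_id", how="left", validate="m:1")
    cols = ["const", "time", *covariate_cols]
    X = pd.DataFrame({"const": 1.0, "time": df["time"].astype(float) / _TIME_SCALE})
    for c in covariate_cols:
        X[c] = df[c].astype(float)
    return df, X[cols]


def fit_lmm(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_cols=("sex", "age", "smoking"),
    reml: bool = False,
) -> LMMFit:
    """Fit the random-intercept + random-slope model by (RE)ML.

    Raises ``ValueError`` on empty data and names the offending column on a
    rank-deficient fixed-effects design.
    """
    if len(observations) == 0:
        raise ValueError("no longitudinal observations to fit")
    covariate_cols = tuple(covariate_cols)
    df, X = _design(observations, covariates, covariate_cols)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            sub = X.iloc[:, : j + 1].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(
                    f"singular fixed-effects design: column '{X.columns[j]}' is "
                    "collinear with earlier columns"
                )

    exog_re = X[["const", "time"]].to_numpy()
    model = sm.MixedLM(
        df["value"].astype(float).to_numpy(),
        X.to_numpy(),
        groups=df["subject_id"].to_numpy(),
        exog_re=exog_re,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, maxiter=500)
    converged = bool(getattr(res, "converged", True))

    # convert the year-scale fit back to month units (copy: the results
    # object computes random effects and llf lazily from fe_params)
    fixed = pd.Series(np.array(res.fe_params, dtype=float), index=list(X.columns))
    fixed["time"] /= _TIME_SCALE
    scale_mat = np.array([[1.0, _TIME_SCALE], [_TIME_SCALE, _TIME_SCALE ** 2]])
    D = np.asarray(res.cov_re, dtype=float) / scale_mat
    D = 0.5 * (D + D.T)
    resid_sd = max(float(np.sqrt(res.scale)), RESID_SD_FLOOR)

    ranefs = pd.DataFrame(
        {sid: np.asarray(re)[:2] for sid, re in res.random_effects.items()}
    ).T
    ranefs.columns = ["b0", "b1"]
    ranefs["b1"] /= _TIME_SCALE
    ranefs.index.name = "subject_id"

    return LMMFit(
        fixed_effects=fixed,
        ranef_cov=D,
        resid_sd=resid_sd,
        subject_ranefs=ranefs,
        loglik=float(res.llf),
        converged=converged,
        covariate_cols=covariate_cols,
    )
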