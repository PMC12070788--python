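"""Shared-random-effects joint model for longitudinal and survival data.

The longitudinal submodel is a linear mixed model
``y_i(t) = x_i(t)'beta + b_i0 + b_i1 t + eps``, with
``b_i ~ N(0, D)`` and ``eps ~ N(0, sigma^2)``.  The survival submodel is a
proportional-hazards model whose hazard depends on the *current value*
``m_i(t)`` of the subject's latent trajectory,

    h_i(t) = h_0(t) * exp(gamma' w_i + alpha * m_i(t)),

with a piecewise-constant baseline hazard ``h_0`` on an equal-event-count
knot grid.  Because ``m_i(t)`` is linear in t, the cumulative hazard has a
closed form on each knot interval.

Estimation is full maximum likelihood.  The per-subject marginal
likelihood integrates the two-dimensional random effect

    p(y_i, T_i, delta_i) = int p(y_i | b) h(T_i | b)^delta S(T_i | b) p(b) db

by pseudo-adaptive Gauss-Hermite quadrature: nodes are placed at each
subject's random-effect posterior implied by the longitudinal data alone
(which is Gaussian and available in closed form) and kept fixed during
optimization via importance reweighting.  Fixed nodes make the marginal
log-likelihood analytically differentiable in every parameter, so the
optimizer (L-BFGS-B) uses exact gradients; an optional re-centering pass
after convergence restores full adaptivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize

from .cox import fit_cox
from .lmm import LMMFit, fit_lmm
from .risk import RiskMatrix

RESID_SD_FLOOR = 1e-6
RATE_FLOOR = 1e-12
# keeps exp() and products of two exp() finite in float64
_EXP_CLIP = 300.0


# ---------------------------------------------------------------------------
# helpers

def _phi1(x):
    """(e^x - 1)/x, stable near 0."""
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 + x / 2.0 + x * x / 6.0, np.expm1(safe) / safe)
    return out


def _phi_pair(x):
    """(e^x - 1)/x and its derivative (e^x (x - 1) + 1)/x^2, sharing expm1."""
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    em = np.expm1(safe)
    phi = np.where(small, 1.0 + x / 2.0 + x * x / 6.0, em / safe)
    # e^x (x-1) + 1 == em * (x - 1) + x
    phip = np.where(
        small, 0.5 + x / 3.0 + x * x / 8.0, (em * (safe - 1.0) + safe) / (safe * safe)
    )
    return phi, phip


def _suff_stats(observations: pd.DataFrame, subject_ids: np.ndarray) -> dict:
    """Per-subject sufficient statistics of the longitudinal data."""
    df = observations.copy()
    df["t2"] = df["time"].astype(float) ** 2
    df["ty"] = df["time"].astype(float) * df["value"].astype(float)
    df["y2"] = df["value"].astype(float) ** 2
    g = df.groupby("subject_id").agg(
        n=("value", "size"),
        St=("time", "sum"),
        St2=("t2", "sum"),
        Sy=("value", "sum"),
        Sty=("ty", "sum"),
        Syy=("y2", "sum"),
    )
    g = g.reindex(subject_ids).fillna(0.0)
    return {k: g[k].to_numpy(dtype=float) for k in g.columns}


def make_baseline_knots(
    event_times: np.ndarray, event_observed: np.ndarray, n_knots: int, horizon: float
) -> np.ndarray:
    """Knot edges with (approximately) equal event counts per interval."""
    ev = np.sort(np.asarray(event_times)[np.asarray(event_observed, dtype=bool)])
    if len(ev) == 0:
        raise ValueError("cannot place baseline knots without observed events")
    qs = np.linspace(0, 1, n_knots + 1)[1:-1]
    inner = np.unique(np.quantile(ev, qs))
    hi = max(float(np.max(event_times)), float(horizon)) + 1e-9
    edges = np.concatenate([[0.0], inner[(inner > 0) & (inner < hi)], [hi]])
    return np.unique(edges)


# ---------------------------------------------------------------------------
# fit result

@dataclass
class JointFit:
    """Fitted joint-model parameter bundle."""

    fixed_effects: pd.Series
    ranef_cov: np.ndarray
    resid_sd: float
    gammas: pd.Series
    alpha: float
    baseline_edges: np.ndarray
    baseline_rates: np.ndarray
    loglik: float
    converged: bool
    n_quad: int
    covariate_cols_long: tuple
    covariate_cols_surv: tuple
    se: dict | None = None
    n_iter: int = 0
    _problem: object = field(default=None, repr=False, compare=False)

    @property
    def alpha_se(self) -> float | None:
        return None if self.se is None else self.se.get("alpha")


# ---------------------------------------------------------------------------
# likelihood machinery

class _JointProblem:
    """Data, quadrature nodes and parameter packing for one joint fit."""

    def __init__(
        self,
        observations: pd.DataFrame,
        subjects: pd.DataFrame,
        covariate_cols_long: tuple,
        covariate_cols_surv: tuple,
        edges: np.ndarray,
        n_quad: int,
    ):
        self.cl = tuple(covariate_cols_long)
        self.cs = tuple(covariate_cols_surv)
        self.edges = np.asarray(edges, dtype=float)
        self.K = len(self.edges) - 1
        self.n_quad = int(n_quad)

        sid = subjects["subject_id"].to_numpy()
        self.subject_ids = sid
        self.N = len(sid)
        st = _suff_stats(observations, sid)
        self.n, self.St, self.St2 = st["n"], st["St"], st["St2"]
        self.Sy, self.Sty, self.Syy = st["Sy"], st["Sty"], st["Syy"]

        self.Wl = subjects[list(self.cl)].to_numpy(dtype=float) if self.cl else np.zeros((self.N, 0))
        self.Ws = subjects[list(self.cs)].to_numpy(dtype=float) if self.cs else np.zeros((self.N, 0))
        self.T = subjects["event_time"].to_numpy(dtype=float)
        self.delta = subjects["event_observed"].to_numpy(dtype=float)

        # interval overlap bounds with [0, T_i] and the event's interval index
        self.s_b = np.minimum(self.edges[:-1][None, :], self.T[:, None])
        self.e_b = np.minimum(self.edges[1:][None, :], self.T[:, None])
        self.Delta = self.e_b - self.s_b
        self.ev_k = np.clip(np.searchsorted(self.edges, self.T, side="right") - 1, 0, self.K - 1)

        # 2-D Gauss-Hermite grid (probabilists'), tensorized
        x, w = hermegauss(self.n_quad)
        U0, U1 = np.meshgrid(x, x, indexing="ij")
        self.u = np.column_stack([U0.ravel(), U1.ravel()])  # (Q, 2)
        lw = np.log(w) - 0.5 * np.log(2.0 * np.pi)
        LW0, LW1 = np.meshgrid(lw, lw, indexing="ij")
        self.logw = (LW0 + LW1).ravel()  # log weights of N(0, I_2) expectation
        self.Q = self.u.shape[0]

        # set by set_nodes()
        self.b0 = self.b1 = self.const_nq = None

        # parameter layout
        pL = 2 + len(self.cl)
        self.pL, self.pS = pL, len(self.cs)
        idx = {}
        k = 0
        idx["beta"] = slice(k, k + pL); k += pL
        idx["log_sigma"] = k; k += 1
        idx["chol"] = slice(k, k + 3); k += 3
        idx["gamma"] = slice(k, k + self.pS); k += self.pS
        idx["alpha"] = k; k += 1
        idx["log_lam"] = slice(k, k + self.K); k += self.K
        self.idx = idx
        self.n_params = k

    # -- quadrature nodes -------------------------------------------------
    def set_nodes(self, beta: np.ndarray, sigma: float, D: np.ndarray) -> None:
        """Center nodes at each subject's LMM random-effect posterior.

        The posterior of b_i given the longitudinal data is Gaussian with
        covariance (Z'Z/sigma^2 + D^-1)^-1; subjects without observations
        get the prior N(0, D).
        """
        s2 = max(sigma, RESID_SD_FLOOR) ** 2
        D = np.asarray(D, dtype=float)
        detD = D[0, 0] * D[1, 1] - D[0, 1] ** 2
        detD = max(detD, 1e-20)
        P = np.array([[D[1, 1], -D[0, 1]], [-D[0, 1], D[0, 0]]]) / detD

        c = beta[0] + (self.Wl @ beta[2:] if self.Wl.shape[1] else 0.0)
        bt = beta[1]
        # precision = Z'Z/s2 + P  (2x2 per subject)
        A00 = self.n / s2 + P[0, 0]
        A01 = self.St / s2 + P[0, 1]
        A11 = self.St2 / s2 + P[1, 1]
        detA = A00 * A11 - A01 ** 2
        S00, S01, S11 = A11 / detA, -A01 / detA, A00 / detA  # posterior cov
        zr0 = (self.Sy - c * self.n - bt * self.St) / s2
        zr1 = (self.Sty - c * self.St - bt * self.St2) / s2
        mu0 = S00 * zr0 + S01 * zr1
        mu1 = S01 * zr0 + S11 * zr1

        # cholesky of the 2x2 posterior covariance, closed form
        L00 = np.sqrt(S00)
        L10 = S01 / L00
        L11 = np.sqrt(np.maximum(S11 - L10 ** 2, 1e-30))

        u0, u1 = self.u[:, 0], self.u[:, 1]
        self.b0 = mu0[:, None] + L00[:, None] * u0[None, :]
        self.b1 = mu1[:, None] + L10[:, None] * u0[None, :] + L11[:, None] * u1[None, :]
        # log w_q - log q0(b_q) folded together: the Gaussian importance
        # density evaluated at its own nodes leaves log|Sigma|/2 + |u|^2/2
        logdetS = np.log(S00 * S11 - S01 ** 2)
        uu = 0.5 * (u0 ** 2 + u1 ** 2)
        self.const_nq = (
            self.logw[None, :] + np.log(2.0 * np.pi) + 0.5 * logdetS[:, None] + uu[None, :]
        )

    # -- packing ----------------------------------------------------------
    def pack(self, beta, sigma, D, gamma, alpha, lam) -> np.ndarray:
        theta = np.empty(self.n_params)
        theta[self.idx["beta"]] = beta
        theta[self.idx["log_sigma"]] = np.log(max(sigma, RESID_SD_FLOOR))
        D = np.asarray(D, dtype=float) + 1e-10 * np.eye(2)
        L = np.linalg.cholesky(D)
        theta[self.idx["chol"]] = [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]
        theta[self.idx["gamma"]] = gamma
        theta[self.idx["alpha"]] = alpha
        theta[self.idx["log_lam"]] = np.log(np.maximum(lam, RATE_FLOOR))
        return theta

    def unpack(self, theta: np.ndarray) -> dict:
        beta = theta[self.idx["beta"]]
        sigma = float(np.exp(theta[self.idx["log_sigma"]]))
        l11, l21, l22 = theta[self.idx["chol"]]
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        D = L @ L.T
        gamma = theta[self.idx["gamma"]]
        alpha = float(theta[self.idx["alpha"]])
        lam = np.exp(theta[self.idx["log_lam"]])
        return dict(beta=beta, sigma=sigma, D=D, L=L, gamma=gamma, alpha=alpha, lam=lam)

    # -- objective --------------------------------------------------------
    def value_and_grad(self, theta: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._value_and_grad(theta)

    def _value_and_grad(self, theta: np.ndarray):
        p = self.unpack(theta)
        beta, sigma, L, gamma, alpha, lam = (
            p["beta"], p["sigma"], p["L"], p["gamma"], p["alpha"], p["lam"],
        )
        s2 = sigma ** 2
        N, Q, K = self.N, self.Q, self.K

        c = beta[0] + (self.Wl @ beta[2:] if self.Wl.shape[1] else 0.0)
        d0 = c[:, None] + self.b0  # marker intercept per node (N, Q)
        d1 = beta[1] + self.b1     # marker slope per node

        n_, St, St2 = self.n[:, None], self.St[:, None], self.St2[:, None]
        Sy, Sty, Syy = self.Sy[:, None], self.Sty[:, None], self.Syy[:, None]
        RSS = Syy - 2 * d0 * Sy - 2 * d1 * Sty + d0 ** 2 * n_ + 2 * d0 * d1 * St + d1 ** 2 * St2
        RSS = np.maximum(RSS, 0.0)
        ly = -0.5 * n_ * np.log(2.0 * np.pi * s2) - RSS / (2.0 * s2)

        # random-effect prior density at nodes
        D = L @ L.T
        detD = D[0, 0] * D[1, 1] - D[0, 1] ** 2
        P = np.array([[D[1, 1], -D[0, 1]], [-D[0, 1], D[0, 0]]]) / detD
        quad = P[0, 0] * self.b0 ** 2 + 2 * P[0, 1] * self.b0 * self.b1 + P[1, 1] * self.b1 ** 2
        lb = -np.log(2.0 * np.pi) - 0.5 * np.log(detD) - 0.5 * quad

        # survival part
        us = self.Ws @ gamma if self.Ws.shape[1] else np.zeros(N)
        eta0 = us[:, None] + alpha * d0
        psi = alpha * d1  # (N, Q)
        A = np.exp(np.clip(psi[:, :, None] * self.s_b[:, None, :], -_EXP_CLIP, _EXP_CLIP))
        x = psi[:, :, None] * self.Delta[:, None, :]
        x = np.clip(x, -_EXP_CLIP, _EXP_CLIP)
        phi, phip = _phi_pair(x)
        g = A * self.Delta[:, None, :] * phi                           # (N, Q, K)
        gp = self.s_b[:, None, :] * g + A * self.Delta[:, None, :] ** 2 * phip
        Gsum = g @ lam
        Gp = gp @ lam
        eh = np.exp(np.clip(eta0, -_EXP_CLIP, _EXP_CLIP))
        H = eh * Gsum
        loglam = np.log(lam)
        d_ = self.delta[:, None]
        ls = d_ * (loglam[self.ev_k][:, None] + eta0 + psi * self.T[:, None]) - H

        term = self.const_nq + ly + lb + ls
        m = np.max(term, axis=1)
        lse = m + np.log(np.sum(np.exp(term - m[:, None]), axis=1))
        loglik = float(np.sum(lse))
        pi = np.exp(term - lse[:, None])  # posterior node weights (N, Q)

        # ---- gradient ----
        grad = np.zeros(self.n_params)
        dmH = d_ - H
        # d/d(marker intercept) and d/d(marker slope) pathways
        dc = -(-2 * Sy + 2 * d0 * n_ + 2 * d1 * St) / (2 * s2) + alpha * dmH
        ds = -(-2 * Sty + 2 * d0 * St + 2 * d1 * St2) / (2 * s2) + (
            d_ * alpha * self.T[:, None] - alpha * eh * Gp
        )
        pc = np.sum(pi * dc, axis=1)  # (N,)
        ps = np.sum(pi * ds, axis=1)
        gb = np.empty(self.pL)
        gb[0] = pc.sum()
        gb[1] = ps.sum()
        if self.pL > 2:
            gb[2:] = self.Wl.T @ pc
        grad[self.idx["beta"]] = gb
        grad[self.idx["log_sigma"]] = np.sum(pi * (-n_ + RSS / s2))

        v0 = P[0, 0] * self.b0 + P[0, 1] * self.b1
        v1 = P[0, 1] * self.b0 + P[1, 1] * self.b1
        M00 = (v0 * v0 - P[0, 0]) * L[0, 0] + (v0 * v1 - P[0, 1]) * L[1, 0]
        M10 = (v0 * v1 - P[0, 1]) * L[0, 0] + (v1 * v1 - P[1, 1]) * L[1, 0]
        M11 = (v1 * v1 - P[1, 1]) * L[1, 1]
        grad[self.idx["chol"]] = [
            np.sum(pi * M00) * L[0, 0],
            np.sum(pi * M10),
            np.sum(pi * M11) * L[1, 1],
        ]

        pH = np.sum(pi * dmH, axis=1)
        if self.pS:
            grad[self.idx["gamma"]] = self.Ws.T @ pH
        grad[self.idx["alpha"]] = np.sum(
            pi * (d_ * (d0 + d1 * self.T[:, None]) - (d0 * H + eh * Gp * d1))
        )
        glam = -np.einsum("nq,nq,nqk->k", pi, eh, g) * lam
        np.add.at(glam, self.ev_k, self.delta)
        grad[self.idx["log_lam"]] = glam

        if not np.isfinite(loglik) or not np.all(np.isfinite(grad)):
            # off-scale trial point during line search: report a large
            # finite value so the optimizer backtracks
            return 1e12, np.where(np.isfinite(grad), -grad, 0.0)
        return -loglik, -grad

    def loglik(self, theta: np.ndarray) -> float:
        return -self.value_and_grad(theta)[0]

    def bounds(self, free: str = "all"):
        lo = np.full(self.n_params, -np.inf)
        hi = np.full(self.n_params, np.inf)
        lo[self.idx["log_sigma"]] = np.log(RESID_SD_FLOOR)
        ch = self.idx["chol"]
        lo[ch.start] = np.log(1e-8); hi[ch.start] = 5.0
        lo[ch.start + 2] = np.log(1e-8); hi[ch.start + 2] = 5.0
        lo[self.idx["alpha"]] = -200.0; hi[self.idx["alpha"]] = 200.0
        lo[self.idx["log_lam"]] = np.log(RATE_FLOOR); hi[self.idx["log_lam"]] = 10.0
        return list(zip(lo, hi))


# ---------------------------------------------------------------------------
# fitting

def _init_lmm(observations, subjects, covariate_cols_long) -> LMMFit:
    try:
        return fit_lmm(observations, subjects, covariate_cols=covariate_cols_long)
    except Exception:
        # degenerate data: OLS fallback with a diffuse random-effect prior
        df = observations.merge(subjects, on="subject_id")
        X = np.column_stack(
            [np.ones(len(df)), df["time"].to_numpy(dtype=float)]
            + [df[c].to_numpy(dtype=float) for c in covariate_cols_long]
        )
        y = df["value"].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sd = max(float(np.std(resid)), RESID_SD_FLOOR)
        return LMMFit(
            fixed_effects=pd.Series(coef, index=["const", "time", *covariate_cols_long]),
            ranef_cov=np.diag([0.01, 1e-5]),
            resid_sd=sd,
            subject_ranefs=pd.DataFrame(columns=["b0", "b1"]),
            loglik=float("nan"),
            converged=False,
            covariate_cols=tuple(covariate_cols_long),
        )


def fit_joint(
    observations: pd.DataFrame,
    subjects: pd.DataFrame,
    covariate_cols_long=("sex", "age", "smoking"),
    covariate_cols_surv=("sex", "age", "smoking"),
    n_quad: int = 9,
    n_knots: int = 10,
    mode: str = "full",
    compute_se: bool = False,
    horizon: float | None = None,
    max_iter: int = 500,
    recenter: bool = True,
) -> JointFit:
    """Fit the joint model by maximum likelihood.

    ``mode="full"`` maximizes over all parameter blocks (longitudinal,
    survival, association, baseline); ``mode="two_stage"`` freezes the
    longitudinal block at its separate mixed-model estimates and maximizes
    only the survival block -- a fast approximation for large repeated
    simulation runs.  Non-convergence is flagged on the returned fit, not
    raised.
    """
    if subjects["event_observed"].astype(bool).sum() == 0:
        raise ValueError("cannot fit the joint model without any observed event")
    if len(observations) == 0:
        raise ValueError("cannot fit the joint model without longitudinal data")
    if mode not in ("full", "two_stage"):
        raise ValueError(f"unknown mode {mode!r}")

    if horizon is None:
        horizon = float(subjects["event_time"].max())
    edges = make_baseline_knots(
        subjects["event_time"].to_numpy(),
        subjects["event_observed"].to_numpy(),
        n_knots,
        horizon,
    )
    prob = _JointProblem(
        observations, subjects, covariate_cols_long, covariate_cols_surv, edges, n_quad
    )

    # --- initial values from the separate submodels
    lmm = _init_lmm(observations, subjects, covariate_cols_long)
    beta0 = lmm.fixed_effects.to_numpy(dtype=float)
    sigma0 = max(lmm.resid_sd, RESID_SD_FLOOR)
    D0 = lmm.ranef_cov + 1e-8 * np.eye(2)
    try:
        cox = fit_cox(
            subjects[["subject_id", "event_time", "event_observed"]],
            subjects[["subject_id", *covariate_cols_surv]],
            feature_cols=covariate_cols_surv,
        )
        gamma0 = cox.coefficients.to_numpy(dtype=float)
    except Exception:
        gamma0 = np.zeros(prob.pS)
    # occurrence/exposure baseline rates
    d_k = np.zeros(prob.K)
    np.add.at(d_k, prob.ev_k, prob.delta)
    exposure = prob.Delta.sum(axis=0)
    lam0 = np.maximum(d_k, 0.5) / np.maximum(exposure, 1e-12)

    prob.set_nodes(beta0, sigma0, D0)
    theta = prob.pack(beta0, sigma0, D0, gamma0, 0.0, lam0)
    bounds = prob.bounds()

    surv_idx = np.r_[
        np.arange(prob.n_params)[prob.idx["gamma"]],
        prob.idx["alpha"],
        np.arange(prob.n_params)[prob.idx["log_lam"]],
    ].astype(int)

    def _optimize(theta0, free_idx, maxiter):
        theta0 = theta0.copy()

        def fg(x):
            th = theta0.copy()
            th[free_idx] = x
            f, gr = prob.value_and_grad(th)
            return f, gr[free_idx]

        res = minimize(
            fg,
            theta0[free_idx],
            jac=True,
            method="L-BFGS-B",
            bounds=[bounds[j] for j in free_idx],
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5, "maxcor": 25},
        )
        out = theta0.copy()
        out[free_idx] = res.x
        return out, res

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # stage 1: survival block only (also the two-stage estimate)
        theta, res = _optimize(theta, surv_idx, min(max_iter, 200))
        n_iter = int(res.nit)
        converged = bool(res.success)
        if mode == "full":
            all_idx = np.arange(prob.n_params)
            theta, res = _optimize(theta, all_idx, max_iter)
            n_iter += int(res.nit)
            converged = bool(res.success)
            if recenter:
                p = prob.unpack(theta)
                prob.set_nodes(p["beta"], p["sigma"], p["D"])
                theta, res = _optimize(theta, all_idx, min(max_iter, 200))
                n_iter += int(res.nit)
                converged = converged and bool(res.success)

    p = prob.unpack(theta)
    loglik = prob.loglik(theta)
    if not np.isfinite(loglik):
        converged = False

    se = None
    if compute_se:
        se = _standard_errors(prob, theta, covariate_cols_long, covariate_cols_surv)

    fit = JointFit(
        fixed_effects=pd.Series(
            p["beta"], index=["const", "time", *covariate_cols_long]
        ),
        ranef_cov=p["D"],
        resid_sd=p["sigma"],
        gammas=pd.Series(p["gamma"], index=list(covariate_cols_surv)),
        alpha=p["alpha"],
        baseline_edges=prob.edges,
        baseline_rates=np.maximum(p["lam"], RATE_FLOOR),
        loglik=loglik,
        converged=converged,
        n_quad=n_quad,
        covariate_cols_long=tuple(covariate_cols_long),
        covariate_cols_surv=tuple(covariate_cols_surv),
        se=se,
        n_iter=n_iter,
        _problem=prob,
    )
    fit._theta = theta
    return fit


def _standard_errors(prob, theta, cl, cs, h: float = 1e-5) -> dict:
    """Observed-information SEs via central differences of the analytic gradient."""
    p = prob.n_params
    Hm = np.zeros((p, p))
    for j in range(p):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        gp = prob.value_and_grad(tp)[1]
        gm = prob.value_and_grad(tm)[1]
        Hm[j] = (gp - gm) / (2 * h)
    Hm = 0.5 * (Hm + Hm.T)
    try:
        cov = np.linalg.inv(Hm)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(Hm)
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = (
        [f"beta_{n}" for n in ["const", "time", *cl]]
        + ["log_sigma", "chol_11", "chol_21", "chol_22"]
        + [f"gamma_{n}" for n in cs]
        + ["alpha"]
        + [f"log_lam_{k}" for k in range(prob.K)]
    )
    return dict(zip(names, sd))


# ---------------------------------------------------------------------------
# dynamic prediction

def predict_risk_joint(
    fit: JointFit,
    observations: pd.DataFrame,
    subjects: pd.DataFrame,
    eval_times: np.ndarray,
    obs_end: float = 60.0,
) -> RiskMatrix:
    """Conditional cumulative risk from the fitted joint model.

    r_i(t) = 1 - E[ S(t|b) / S(obs_end|b) | history, T_i > obs_end ], the
    expectation taken over the subject's random-effect posterior given the
    in-window biomarker history, on the same quadrature grid as fitting.
    """
    eval_times = np.asarray(eval_times, dtype=int)
    early = subjects["event_observed"].astype(bool) & (
        subjects["event_time"] <= obs_end
    )
    if early.any():
        raise ValueError(
            f"{int(early.sum())} subjects have an event before obs_end={obs_end}; "
            "filter to the at-risk set first"
        )

    obs = observations[observations["time"] <= obs_end]
    # dummy survival columns: only covariates and histories are used below
    prob = _JointProblem(
        obs,
        subjects,
        fit.covariate_cols_long,
        fit.covariate_cols_surv,
        fit.baseline_edges,
        fit.n_quad,
    )
    beta = fit.fixed_effects.to_numpy(dtype=float)
    prob.set_nodes(beta, fit.resid_sd, fit.ranef_cov)

    s2 = fit.resid_sd ** 2
    c = beta[0] + (prob.Wl @ beta[2:] if prob.Wl.shape[1] else 0.0)
    d0 = c[:, None] + prob.b0
    d1 = beta[1] + prob.b1
    n_, St, St2 = prob.n[:, None], prob.St[:, None], prob.St2[:, None]
    Sy, Sty, Syy = prob.Sy[:, None], prob.Sty[:, None], prob.Syy[:, None]
    RSS = Syy - 2 * d0 * Sy - 2 * d1 * Sty + d0 ** 2 * n_ + 2 * d0 * d1 * St + d1 ** 2 * St2
    ly = -0.5 * n_ * np.log(2 * np.pi * s2) - np.maximum(RSS, 0.0) / (2 * s2)
    D = fit.ranef_cov
    detD = D[0, 0] * D[1, 1] - D[0, 1] ** 2
    P = np.array([[D[1, 1], -D[0, 1]], [-D[0, 1], D[0, 0]]]) / detD
    quad = P[0, 0] * prob.b0 ** 2 + 2 * P[0, 1] * prob.b0 * prob.b1 + P[1, 1] * prob.b1 ** 2
    lb = -np.log(2 * np.pi) - 0.5 * np.log(detD) - 0.5 * quad

    logrho = prob.const_nq + ly + lb
    m = np.max(logrho, axis=1, keepdims=True)
    rho = np.exp(logrho - m)
    rho /= rho.sum(axis=1, keepdims=True)  # posterior-from-history weights

    gamma = fit.gammas.to_numpy(dtype=float)
    lam = fit.baseline_rates
    edges = fit.baseline_edges
    us = prob.Ws @ gamma if prob.Ws.shape[1] else np.zeros(prob.N)
    eta0 = us[:, None] + fit.alpha * d0
    psi = fit.alpha * d1  # (N, Q)

    # cumulative hazard at knot edges, then interpolate analytically to t
    lo = edges[:-1][None, None, :]
    hi_ = edges[1:][None, None, :]
    x_lo = np.clip(psi[:, :, None] * lo, -_EXP_CLIP, _EXP_CLIP)
    dlt = hi_ - lo
    xx = np.clip(psi[:, :, None] * dlt, -_EXP_CLIP, _EXP_CLIP)
    g_full = np.exp(x_lo) * dlt * _phi1(xx)  # (N, Q, K)
    cumH_edges = np.concatenate(
        [np.zeros((prob.N, prob.Q, 1)), np.cumsum(g_full * lam[None, None, :], axis=2)],
        axis=2,
    )  # before exp(eta0) factor

    times = np.concatenate([[float(obs_end)], eval_times.astype(float)])
    kk = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, prob.K - 1)
    S = np.empty((prob.N, len(times), prob.Q))
    eh = np.exp(np.clip(eta0, -_EXP_CLIP, _EXP_CLIP))
    for j, (t, k) in enumerate(zip(times, kk)):
        x_part = np.clip(psi * (t - edges[k]), -_EXP_CLIP, _EXP_CLIP)
        g_part = np.exp(np.clip(psi * edges[k], -_EXP_CLIP, _EXP_CLIP)) * (
            t - edges[k]
        ) * _phi1(x_part)
        Ht = eh * (cumH_edges[:, :, k] + lam[k] * g_part)
        S[:, j, :] = np.exp(-Ht)

    num = np.einsum("nq,ntq->nt", rho, S)
    denom = num[:, 0][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 - num[:, 1:] / denom
    r = np.clip(r, 0.0, 1.0)
    # guard monotonicity against roundoff
    r = np.maximum.accumulate(r, axis=1)
    return RiskMatrix(prob.subject_ids, eval_times, r)
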