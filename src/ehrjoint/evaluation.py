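"""Time-varying concordance index and the at-risk evaluation protocol.

At evaluation month t with window ``interval``, the index compares

* S1: subjects with an observed diagnosis in [t - interval, t], against
* S2: subjects diagnosis-free through [0, t + interval],

and counts the fraction of (S1, S2) pairs in which the predicted risk of
the pre-diagnosis subject strictly exceeds that of the still-healthy
subject (ties count as discordant, per the strict indicator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk import RiskMatrix


@dataclass
class TvcResult:
    eval_times: np.ndarray
    tvc: np.ndarray  # NaN where undefined (empty S1 or S2)
    n1: np.ndarray
    n2: np.ndarray
    interval: int
    mean_tvc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.eval_times, "tvc": self.tvc, "n1": self.n1, "n2": self.n2}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False)


def filter_at_risk(survival: pd.DataFrame, obs_end: float) -> pd.DataFrame:
    """Subjects still event-free at the end of the observation window.

    Only these subjects enter risk prediction and tvC computation: a
    subject diagnosed during the observation window cannot be scored by a
    model that uses the full window, so excluding them keeps the model
    comparison fair.
    """
    return survival[survival["event_time"] > obs_end].reset_index(drop=True)


def _tvc_from_arrays(r, e, d, t, interval, horizon):
    s1 = d & (e >= t - interval) & (e <= t)
    end = min(t + interval, horizon)
    s2 = ~(d & (e <= t + interval)) & (e >= end)
    n1, n2 = int(s1.sum()), int(s2.sum())
    if n1 == 0 or n2 == 0:
        return float("nan"), n1, n2
    r1 = np.sort(r[s1])
    r2 = np.sort(r[s2])
    # concordant pairs r_k > r_l by merge: per k, count of l with r_l < r_k
    concordant = int(np.searchsorted(r2, r1, side="left").sum())
    return concordant / (n1 * n2), n1, n2


def _aligned(risks: RiskMatrix, survival: pd.DataFrame):
    surv = survival.set_index("subject_id").loc[risks.subject_ids]
    e = surv["event_time"].to_numpy(dtype=float)
    d = surv["event_observed"].to_numpy().astype(bool)
    return e, d


def tvc_at(
    risks: RiskMatrix,
    survival: pd.DataFrame,
    t: int,
    interval: int = 12,
    horizon: float | None = None,
) -> tuple[float, int, int]:
    """Time-varying C-index at month ``t``; (nan, n1, n2) when undefined."""
    e, d = _aligned(risks, survival)
    if horizon is None:
        horizon = float(e.max())
    return _tvc_from_arrays(risks.at_time(t), e, d, t, interval, horizon)


def tvc_curve(
    risks: RiskMatrix,
    survival: pd.DataFrame,
    t_start: int = 60,
    t_stop: int = 120,
    interval: int = 12,
    horizon: float | None = None,
    mode: str = "mean",
) -> TvcResult:
    """tvC over integer months [t_start, t_stop] plus its follow-up mean.

    ``mode="mean"`` averages over the defined time points; ``mode="literal"``
    divides the sum by (t_stop - t_start) exactly as the closed-form
    follow-up mean is printed (which counts one more term than its divisor).
    """
    if t_start >= t_stop:
        raise ValueError("t_start must be before t_stop")
    times = np.arange(t_start, t_stop + 1)
    e, d = _aligned(risks, survival)
    if horizon is None:
        horizon = float(e.max())
    vals = np.empty(len(times))
    n1s = np.empty(len(times), dtype=int)
    n2s = np.empty(len(times), dtype=int)
    for j, t in enumerate(times):
        vals[j], n1s[j], n2s[j] = _tvc_from_arrays(
            risks.at_time(t), e, d, t, interval, horizon
        )
    defined = ~np.isnan(vals)
    if not defined.any():
        mean = float("nan")
    elif mode == "literal":
        mean = float(np.nansum(vals) / (t_stop - t_start))
    else:
        mean = float(np.mean(vals[defined]))
    return TvcResult(times, vals, n1s, n2s, interval, mean)


def mean_tvc(
    risks: RiskMatrix,
    survival: pd.DataFrame,
    t_start: int = 60,
    t_stop: int = 120,
    interval: int = 12,
    horizon: float | None = None,
    mode: str = "mean",
) -> float:
    """Follow-up mean of the time-varying C-index (see ``tvc_curve``)."""
    return tvc_curve(risks, survival, t_start, t_stop, interval, horizon, mode).mean_tvc
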