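"""Per-subject dynamic risk matrices over the follow-up window."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RiskMatrix:
    """Predicted cumulative risk r_i(t) per subject and evaluation month.

    Risks follow the conditional cumulative-risk convention: r_i(t) is the
    probability of an event in (t_end, t] given event-free status at the
    end of the observation window, so every row is nondecreasing in t and
    starts at 0.
    """

    subject_ids: np.ndarray
    eval_times: np.ndarray
    risks: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.eval_times = np.asarray(self.eval_times, dtype=int)
        self.risks = np.asarray(self.risks, dtype=float)
        if self.risks.shape != (len(self.subject_ids), len(self.eval_times)):
            raise ValueError(
                f"risks shape {self.risks.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.eval_times)} times"
            )

    def validate(self, atol: float = 1e-8) -> None:
        if np.any(np.diff(self.risks, axis=1) < -atol):
            raise ValueError("risk rows must be nondecreasing in t")
        if np.any(np.abs(self.risks[:, 0]) > atol):
            raise ValueError("risk at the first evaluation time must be 0")

    def at_time(self, t: int) -> np.ndarray:
        """Risk column at month ``t``."""
        idx = np.nonzero(self.eval_times == t)[0]
        if len(idx) == 0:
            raise KeyError(f"time {t} not among evaluation times")
        return self.risks[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.risks, columns=[str(t) for t in self.eval_times])
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskMatrix":
        df = pd.read_csv(path)
        times = np.array([int(c) for c in df.columns[1:]])
        return cls(df["subject_id"].to_numpy(), times, df.iloc[:, 1:].to_numpy())
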