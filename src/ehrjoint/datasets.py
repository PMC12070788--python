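"""External example data loaders.

The Mayo Clinic primary biliary cirrhosis (PBC) trial data — the classic
positive example for joint modelling, with serum bilirubin as the
longitudinal marker — ship with the R ``survival`` package
(``pbc``/``pbcseq``, the 312 randomized-trial participants with
sequential laboratory visits).  :func:`load_pbc` extracts them at run
time through ``Rscript``; no data files are stored in this package.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0

_R_EXPORT = """
suppressMessages(library(survival))
seq <- pbcseq[, c("id", "day", "bili")]
write.csv(seq, file.path("{dir}", "pbc_long.csv"), row.names = FALSE)
base <- pbc[pbc$id %in% unique(pbcseq$id), c("id", "time", "status", "sex", "age")]
write.csv(base, file.path("{dir}", "pbc_surv.csv"), row.names = FALSE)
"""


class DatasetUnavailable(RuntimeError):
    pass


def load_pbc(horizon_months: float = 120.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PBC sequential bilirubin data in this package's long format.

    Returns ``(longitudinal, survival)``: raw (unnormalized) bilirubin in
    mg/dl with times in months since enrollment, and a survival table in
    which the event is death; deaths after ``horizon_months`` are treated
    as censored at the horizon (a 10-year study frame).  Raises
    :class:`DatasetUnavailable` when Rscript or the survival package is
    missing.
    """
    with tempfile.TemporaryDirectory() as tmp:
        script = _R_EXPORT.format(dir=tmp)
        try:
            proc = subprocess.run(
                ["Rscript", "--vanilla", "-e", script],
                capture_output=True, text=True, timeout=300,
            )
        except (OSError, subprocess.TimeoutExpired) as err:
            raise DatasetUnavailable(f"Rscript unavailable: {err}") from err
        if proc.returncode != 0:
            raise DatasetUnavailable(
                f"R export failed: {proc.stderr.strip()[:500]}"
            )
        seq = pd.read_csv(Path(tmp) / "pbc_long.csv")
        base = pd.read_csv(Path(tmp) / "pbc_surv.csv")

    longitudinal = pd.DataFrame(
        {
            "subject_id": seq["id"].astype(int),
            "time": seq["day"].astype(float) / DAYS_PER_MONTH,
            "value": seq["bili"].astype(float),
        }
    )
    months = base["time"].astype(float) / DAYS_PER_MONTH
    death = base["status"].astype(int) == 2
    event_time = months.clip(upper=horizon_months)
    event_observed = death & (months <= horizon_months)
    survival = pd.DataFrame(
        {
            "subject_id": base["id"].astype(int),
            "event_time": event_time,
            "event_observed": event_observed,
            "sex": (base["sex"].astype(str) == "m").astype(int),
            "age": base["age"].astype(float),
        }
    )
    return longitudinal, survival
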