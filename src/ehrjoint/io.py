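"""Long-format CSV input/output with strict validation.

All time columns are in months.  Formats:

* longitudinal: ``subject_id,time,value``
* survival: ``subject_id,event_time,event_observed`` (0/1/true/false)
* covariates: ``subject_id`` plus numeric covariate columns
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ScenarioConfig
from .simulator import Cohort, COVARIATE_COLUMNS, TRUTH_COLUMNS


class FormatError(ValueError):
    """Raised on malformed input files."""


_BOOL_TOKENS = {"0": False, "1": True, "false": False, "true": True,
                "False": False, "True": True}


def _read_checked(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    cols = list(df.columns)
    if len(set(cols)) != len(cols):
        raise FormatError(f"{path}: duplicate header column")
    missing = [c for c in required_cols if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _subject_ids(df):
    """Subject ids as integers when they all look numeric, else strings."""
    ids = df["subject_id"]
    converted = pd.to_numeric(ids, errors="coerce")
    if converted.notna().all():
        return converted.astype(int)
    return ids


def _numeric(df, col, path):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise FormatError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"'{col}' on line {line}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise FormatError(f"{path}: missing value in column '{col}' on line {line}")
    return vals


def read_longitudinal_csv(path) -> pd.DataFrame:
    """Read and validate a long-format biomarker table."""
    df = _read_checked(path, ["subject_id", "time", "value"])
    out = pd.DataFrame(
        {
            "subject_id": _subject_ids(df),
            "time": _numeric(df, "time", path),
            "value": _numeric(df, "value", path),
        }
    )
    return out


def read_survival_csv(path) -> pd.DataFrame:
    """Read and validate a survival table (times >= 0, boolean events)."""
    df = _read_checked(path, ["subject_id", "event_time", "event_observed"])
    times = _numeric(df, "event_time", path)
    if (times < 0).any():
        line = int((times < 0).idxmax()) + 2
        raise FormatError(f"{path}: negative event_time on line {line}")
    events = []
    for i, tok in enumerate(df["event_observed"]):
        t = str(tok).strip()
        if t not in _BOOL_TOKENS:
            raise FormatError(
                f"{path}: unknown boolean token {tok!r} in event_observed on "
                f"line {i + 2}"
            )
        events.append(_BOOL_TOKENS[t])
    return pd.DataFrame(
        {"subject_id": _subject_ids(df), "event_time": times,
         "event_observed": np.array(events, dtype=bool)}
    )


def read_covariates_csv(path) -> pd.DataFrame:
    df = _read_checked(path, ["subject_id"])
    out = {"subject_id": _subject_ids(df)}
    for c in df.columns:
        if c != "subject_id":
            out[c] = _numeric(df, c, path)
    return pd.DataFrame(out)


def write_cohort(cohort: Cohort, out_dir, with_truth: bool = False) -> None:
    """Serialize a cohort: observations.csv, subjects.csv, config.yaml.

    Latent generative truth columns are written only when ``with_truth``
    is set, to keep them out of accidental model fits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.observations.to_csv(out / "observations.csv", index=False)
    cols = ["subject_id", "event_time", "event_observed", *COVARIATE_COLUMNS]
    if with_truth:
        cols += TRUTH_COLUMNS
    subj = cohort.subjects[cols].copy()
    subj["event_observed"] = subj["event_observed"].astype(int)
    subj.to_csv(out / "subjects.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, ScenarioConfig | None]:
    """Read back (observations, subjects, config) written by write_cohort."""
    in_dir = Path(in_dir)
    obs = read_longitudinal_csv(in_dir / "observations.csv")
    subj = pd.read_csv(in_dir / "subjects.csv")
    subj["event_observed"] = subj["event_observed"].astype(bool)
    config = None
    cfg_path = in_dir / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = ScenarioConfig.from_dict(yaml.safe_load(fh))
    return obs, subj, config
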