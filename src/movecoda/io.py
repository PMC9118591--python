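"""CSV readers/writers with row-level validation.

All interchange is plain UTF-8 CSV with ISO-8601 minute-resolution
timestamps.  Readers validate schemas and report offending rows by their
1-based file line number (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .walkability import INDICATOR_COLUMNS

__all__ = [
    "read_epoch_csv",
    "read_indicator_csv",
    "read_cohort_csv",
    "read_covariate_csv",
    "write_behaviour_csv",
    "write_scores_csv",
]

EPOCH_COLUMNS = ("subject_id", "timestamp", "cpm")
COVARIATE_COLUMNS = ("subject_id", "sex", "age", "bmi_z", "puberty",
                     "summer", "parent_edu", "safety")


class CsvValidationError(ValueError):
    """Raised when a CSV fails schema or row validation."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvValidationError(
            f"{path}: missing required column(s): {missing}")


def _lines(idx) -> list[int]:
    """Map DataFrame positions to file line numbers (header is line 1)."""
    return [int(i) + 2 for i in idx]


def read_epoch_csv(path) -> pd.DataFrame:
    """Read a long epoch table: subject_id, timestamp (ISO-8601), cpm."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EPOCH_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = np.flatnonzero(ts.isna())
    if bad.size:
        raise CsvValidationError(
            f"{path}: unparseable timestamp(s) at line(s) "
            f"{_lines(bad[:10])}")
    df["timestamp"] = ts
    cpm = pd.to_numeric(df["cpm"], errors="coerce")
    bad = np.flatnonzero(cpm.isna() | (cpm < 0))
    if bad.size:
        raise CsvValidationError(
            f"{path}: negative or non-numeric cpm at line(s) "
            f"{_lines(bad[:10])}")
    df["cpm"] = cpm.astype(np.int64)
    for sid, grp in df.groupby("subject_id", sort=False):
        diffs = grp["timestamp"].diff().dropna()
        bad = np.flatnonzero(diffs.dt.total_seconds() <= 0)
        if bad.size:
            pos = grp.index[bad[0] + 1]
            raise CsvValidationError(
                f"{path}: out-of-order timestamp for subject {sid} "
                f"at line {int(pos) + 2}")
    return df


def read_indicator_csv(path) -> pd.DataFrame:
    """Read the six-indicator neighborhood table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id",) + INDICATOR_COLUMNS, path)
    for c in INDICATOR_COLUMNS:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(vals.isna())
        if bad.size:
            raise CsvValidationError(
                f"{path}: missing/non-numeric {c} at line(s) "
                f"{_lines(bad[:10])}")
        df[c] = vals
    bad = np.flatnonzero((df["park_area_ratio"] < 0)
                         | (df["park_area_ratio"] > 1))
    if bad.size:
        raise CsvValidationError(
            f"{path}: park_area_ratio outside [0, 1] at line(s) "
            f"{_lines(bad[:10])}")
    return df


def read_covariate_csv(path) -> pd.DataFrame:
    """Read the subject covariate table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COVARIATE_COLUMNS, path)
    bad = np.flatnonzero(~df["sex"].isin(["F", "M"]))
    if bad.size:
        raise CsvValidationError(
            f"{path}: sex must be 'F' or 'M' at line(s) {_lines(bad[:10])}")
    if df[list(COVARIATE_COLUMNS)].isna().any().any():
        bad = np.flatnonzero(df[list(COVARIATE_COLUMNS)].isna().any(axis=1))
        raise CsvValidationError(
            f"{path}: missing covariate value(s) at line(s) "
            f"{_lines(bad[:10])}")
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    """Read an assembled cohort table (covariates + walkability +
    behaviour composition in minutes)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, COVARIATE_COLUMNS + ("walkability", "sleep", "SB", "LPA", "MVPA"),
        path)
    comp = df[["sleep", "SB", "LPA", "MVPA"]].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.all(comp > 0, axis=1))
    if bad.size:
        raise CsvValidationError(
            f"{path}: non-positive behaviour duration(s) at line(s) "
            f"{_lines(bad[:10])}")
    return df


def write_behaviour_csv(behaviour: pd.DataFrame, path) -> None:
    behaviour.to_csv(path, index=False)


def write_scores_csv(scores, path, sidecar_path=None) -> None:
    """Write walkability scores plus a JSON sidecar with loadings,
    variance share and Spearman correlations."""
    df = pd.DataFrame({"subject_id": scores.scores.index,
                       "walkability": scores.scores.to_numpy()})
    df.to_csv(path, index=False)
    if sidecar_path is not None:
        payload = {
            "loadings": scores.loadings.to_dict(),
            "variance_explained": scores.variance_explained,
            "spearman_rho": scores.spearman_rho.to_dict(),
            "eigenvalues": list(map(float, scores.eigenvalues)),
            "n_retained_scree": scores.n_retained_scree,
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=2))
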