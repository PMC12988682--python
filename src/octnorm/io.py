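"""Cohort CSV and fit JSON serialization.

Cohort schema: ``eye_id,age,disc_area,cohort,<metric columns...>`` with
metric names drawn from the registry.  Floats are written with 6 significant
digits, so a write/read round trip preserves values to that precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import METRICS

__all__ = ["read_cohort_csv", "write_cohort_csv", "save_fits_json", "load_fits_json"]

_REQUIRED = ("eye_id", "age", "disc_area", "cohort")


class CohortCSVError(ValueError):
    pass


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table; errors carry the offending file line."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortCSVError(f"{path}: missing required columns {missing}")
    unknown = [
        c for c in df.columns if c not in _REQUIRED and c not in METRICS
    ]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown metric columns {unknown}")
        df = df.drop(columns=unknown)
    numeric_cols = [c for c in df.columns if c not in ("eye_id", "cohort")]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        if bad.any() or converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise CohortCSVError(
                f"{path}, line {row + 2}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}"
            )
        df[col] = converted
    return df


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.6g")


def save_fits_json(fits, path, **extra) -> None:
    """Serialize a list of fit objects (anything with ``to_dict``)."""
    payload = {"fits": [f.to_dict() for f in fits], **extra}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fits_json(path) -> dict:
    return json.loads(Path(path).read_text())
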