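"""Green/yellow/red flagging of test eyes against percentile cutoff lines.

An eye's metric value is compared with the 5th- and 1st-percentile cutoffs
evaluated at the eye's own covariates: strictly below the 5th percentile is
yellow, strictly below the 1st is red, otherwise green.  A value exactly on
a cutoff is not "below" it, so ties resolve toward the less abnormal colour;
with continuous data ties have probability zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .quantile import QuantileFit, QuantileError

__all__ = [
    "CutoffSet",
    "QuantileCrossingError",
    "evaluate_cutoff",
    "classify_eye",
    "flag_cohort",
    "adjust_for_disc_area",
    "COLORS",
]

COLORS = ("green", "yellow", "red")
REQUIRED_TAUS = (0.50, 0.05, 0.01)


class QuantileCrossingError(ValueError):
    """Raised when the 1st-percentile cutoff exceeds the 5th at some eye."""

    def __init__(self, cutoff_1: float, cutoff_5: float, context: str = ""):
        self.cutoff_1 = cutoff_1
        self.cutoff_5 = cutoff_5
        msg = f"crossed cutoffs: 1st percentile {cutoff_1:.3f} > 5th {cutoff_5:.3f}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass
class CutoffSet:
    """Cutoff lines at the 50th/5th/1st percentiles for one metric and one
    reference database, fitted by one method (quantile or gaussian)."""

    metric: str
    method: str  # "quantile" | "gaussian"
    fits: Mapping[float, QuantileFit]  # keyed by tau
    rdb: str  # source reference-database label

    def __post_init__(self) -> None:
        missing = [t for t in REQUIRED_TAUS if t not in self.fits]
        if missing:
            raise ValueError(f"CutoffSet missing taus {missing}")
        specs = {f.spec.name for f in self.fits.values()}
        if len(specs) != 1 or self.metric not in specs:
            raise ValueError("all fits in a CutoffSet must share one metric spec")


def evaluate_cutoff(fit: QuantileFit, age, disc_area=None) -> np.ndarray:
    """Cutoff line value intercept + sum slope_i * covariate_i."""
    return fit.predict(age, disc_area=disc_area)


def classify_eye(value: float, cutoff_1: float, cutoff_5: float) -> str:
    """Strict-inequality flag rule; raises on crossed cutoffs."""
    if cutoff_1 > cutoff_5:
        raise QuantileCrossingError(cutoff_1, cutoff_5)
    if value < cutoff_1:
        return "red"
    if value < cutoff_5:
        return "yellow"
    return "green"


def flag_cohort(
    records: pd.DataFrame, cutoffs: CutoffSet, on_crossing: str = "raise"
) -> tuple[pd.DataFrame, dict]:
    """Flag every eye in the cohort for one metric.

    Returns the per-eye assignment table
    ``eye_id, metric, rdb, value, cutoff_5, cutoff_1, color`` and a color
    count dict.  Raises on missing metric values.

    Crossed cutoffs (1st percentile above the 5th at an eye's covariates — a
    pathology of noisy tail fits evaluated at extreme covariates) raise by
    default.  ``on_crossing="log"`` instead classifies the affected eyes
    against the sorted pair of cutoffs and reports them under
    ``counts["crossed_eyes"]``, so a study over many eyes can proceed while
    the pathology stays visible.
    """
    if on_crossing not in ("raise", "log"):
        raise ValueError(f"on_crossing must be 'raise' or 'log', got {on_crossing!r}")
    metric = cutoffs.metric
    if metric not in records.columns:
        raise QuantileError(f"metric {metric!r} absent from cohort")
    if records[metric].isna().any():
        bad = records.loc[records[metric].isna(), "eye_id"].tolist()
        raise QuantileError(f"metric {metric!r} missing for eyes {bad[:10]}")
    spec = cutoffs.fits[0.05].spec
    kwargs = {}
    if "disc_area" in spec.covariates:
        kwargs["disc_area"] = records["disc_area"].to_numpy(dtype=float)
    ages = records["age"].to_numpy(dtype=float)
    c5 = np.asarray(evaluate_cutoff(cutoffs.fits[0.05], ages, **kwargs), dtype=float)
    c1 = np.asarray(evaluate_cutoff(cutoffs.fits[0.01], ages, **kwargs), dtype=float)
    crossed = c1 > c5 + 1e-9
    if crossed.any() and on_crossing == "raise":
        i = int(np.argmax(crossed))
        raise QuantileCrossingError(
            float(c1[i]), float(c5[i]),
            context=f"eye {records['eye_id'].iloc[i]} age {ages[i]:.1f}",
        )
    lo = np.minimum(c1, c5)
    hi = np.maximum(c1, c5)
    values = records[metric].to_numpy(dtype=float)
    color = np.where(values < lo, "red", np.where(values < hi, "yellow", "green"))
    out = pd.DataFrame(
        {
            "eye_id": records["eye_id"].to_numpy(),
            "metric": metric,
            "rdb": cutoffs.rdb,
            "value": values,
            "cutoff_5": c5,
            "cutoff_1": c1,
            "color": color,
        }
    )
    counts: dict = {c: int(np.sum(color == c)) for c in COLORS}
    if crossed.any():
        counts["crossed_eyes"] = records.loc[crossed, "eye_id"].tolist()
    return out, counts


def adjust_for_disc_area(value, disc_area, disc_ref: float, disc_slope: float):
    """Project a thickness to the reference disc area for 2-D display:
    value - disc_slope * (disc_area - disc_ref).

    With the fit's own disc slope, comparing the adjusted value against the
    age-only cutoff line at disc_ref is algebraically identical to comparing
    the raw value against the full cutoff plane.
    """
    value = np.asarray(value, dtype=float)
    disc_area = np.asarray(disc_area, dtype=float)
    if not (np.all(np.isfinite(value)) and np.all(np.isfinite(disc_area))):
        raise ValueError("adjust_for_disc_area requires finite inputs")
    return value - disc_slope * (disc_area - disc_ref)
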