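"""Monte Carlo subsampling of a large reference database.

Repeatedly draw m eyes without replacement from the source cohort, refit the
QRLs at each tau, and collect the empirical sampling distribution of every
coefficient.  The 95% interval is read off the 2.5th/97.5th percentiles of
the draws (percentile method, linear interpolation between order statistics).
Checking whether an independently fitted small database's coefficients fall
inside those intervals asks whether that database behaves like a random
m-eye sample of the large one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantile import QuantileFit, SingularDesignError, fit_qrl
from .registry import MetricSpec

__all__ = [
    "MCConfig",
    "MCDistribution",
    "run_subsample_study",
    "percentile_interval",
    "membership_check",
]

_MAX_REDRAWS = 10


def _draw_indices(rng: np.random.Generator, n: int, m: int, replacement: bool) -> np.ndarray:
    """One iteration's eye indices; distinct when sampling without replacement."""
    return rng.choice(n, size=m, replace=replacement)


@dataclass
class MCConfig:
    m: int = 398
    iterations: int = 1000
    taus: tuple[float, ...] = (0.05, 0.01)
    seed: int = 0
    replacement: bool = False
    level: float = 0.95

    def validate(self, source_n: int) -> None:
        if not 1 < self.m <= source_n:
            raise ValueError(f"need 1 < m <= {source_n}, got m={self.m}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class MCDistribution:
    """Sampling distribution of QRL coefficients under m-eye subsampling."""

    metric: str
    config: MCConfig
    # estimates[tau][coef] -> array of length iterations
    estimates: dict[float, dict[str, np.ndarray]]
    redraws: int = 0
    notes: list[str] = field(default_factory=list)

    def ci(self, tau: float, coef: str) -> tuple[float, float]:
        return percentile_interval(self.estimates[tau][coef], self.config.level)

    def mean(self, tau: float, coef: str) -> float:
        return float(np.mean(self.estimates[tau][coef]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tau, by_coef in self.estimates.items():
            for coef, vals in by_coef.items():
                for it, v in enumerate(vals):
                    rows.append((self.metric, tau, coef, it, v))
        return pd.DataFrame(
            rows, columns=["metric", "tau", "coefficient", "iteration", "estimate"]
        )


def run_subsample_study(
    source_records: pd.DataFrame, spec: MetricSpec, mc: MCConfig
) -> MCDistribution:
    """Draw ``iterations`` subsamples of size m and refit the QRLs.

    Deterministic given ``mc.seed``.  A subsample with a singular design is
    re-drawn (up to 10 times) and counted.
    """
    n = len(source_records)
    mc.validate(n)
    rng = np.random.default_rng(mc.seed)
    names = ("intercept",) + spec.covariates
    estimates = {
        tau: {name: np.empty(mc.iterations) for name in names} for tau in mc.taus
    }
    redraws = 0
    notes: list[str] = []
    if mc.iterations == 1:
        notes.append("single iteration: intervals are degenerate")
    for it in range(mc.iterations):
        for attempt in range(_MAX_REDRAWS + 1):
            idx = _draw_indices(rng, n, mc.m, mc.replacement)
            sub = source_records.iloc[idx]
            try:
                fits = {tau: fit_qrl(sub, spec, tau) for tau in mc.taus}
                break
            except SingularDesignError:
                redraws += 1
        else:
            raise SingularDesignError(
                f"iteration {it}: {_MAX_REDRAWS} consecutive singular subsamples"
            )
        for tau, fit in fits.items():
            for name in names:
                estimates[tau][name][it] = fit.coefficients[name]
    return MCDistribution(spec.name, mc, estimates, redraws=redraws, notes=notes)


def percentile_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval via linear interpolation of order statistics
    (the default quantile definition: position (k-1)/(n-1))."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("percentile interval needs >= 2 samples")
    alpha = 1.0 - level
    return (
        float(np.quantile(x, alpha / 2.0, method="linear")),
        float(np.quantile(x, 1.0 - alpha / 2.0, method="linear")),
    )


def membership_check(
    fits: dict[float, QuantileFit], dist: MCDistribution
) -> tuple[pd.DataFrame, dict]:
    """Is each small-database coefficient inside the subsampling 95% CI?

    Interval endpoints count as inside (closed intervals).  Returns a table
    with one row per (tau, coefficient) and aggregate counts for slopes and
    intercepts.
    """
    rows = []
    for tau, fit in fits.items():
        if tau not in dist.estimates:
            raise ValueError(f"tau {tau} not present in the MC distribution")
        if fit.metric != dist.metric:
            raise ValueError(
                f"membership: fit metric {fit.metric} != distribution {dist.metric}"
            )
        for coef, value in fit.coefficients.items():
            lo, hi = dist.ci(tau, coef)
            rows.append(
                {
                    "metric": fit.metric,
                    "tau": tau,
                    "coefficient": coef,
                    "estimate": value,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "inside": bool(lo <= value <= hi),
                }
            )
    table = pd.DataFrame(rows)
    counts = {
        "n_checks": len(table),
        "n_inside": int(table["inside"].sum()),
        "slopes_inside": int(
            table.loc[table["coefficient"] != "intercept", "inside"].sum()
        ),
        "slopes_total": int((table["coefficient"] != "intercept").sum()),
        "intercepts_inside": int(
            table.loc[table["coefficient"] == "intercept", "inside"].sum()
        ),
        "intercepts_total": int((table["coefficient"] == "intercept").sum()),
    }
    return table, counts
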