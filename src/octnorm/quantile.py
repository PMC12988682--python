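"""Linear quantile regression for age-conditional percentile cutoffs.

The tau-th quantile regression line (QRL) minimises the pinball (check)
loss  sum_i rho_tau(y_i - x_i'b)  with  rho_tau(u) = u*(tau - 1[u<0]).
cpRNFL-family metrics are regressed on age and disc area, GCL+ metrics on
age only.  The minimisation is solved exactly as a linear program in its
dual form

    max_d  y'd   s.t.  X'd = 0,   d_i in [tau-1, tau],

whose equality-constraint multipliers are the primal coefficients and whose
solution vector d supplies the regression rank scores used by the
rank-inversion confidence intervals.

Confidence intervals per coefficient come from either

* ``rank_inversion`` — inversion of the Gutenbrunner-Jureckova-Koenker
  regression rank-score test with the sign (tau-quantile) score function,
  bisected per coefficient while the others stay at their point estimates; or
* ``bootstrap`` — case resampling with the percentile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .registry import MetricSpec

__all__ = [
    "QuantileFit",
    "CoefficientCI",
    "QuantileError",
    "SingularDesignError",
    "pinball_loss",
    "design_matrix",
    "fit_qrl",
    "coefficient_ci",
    "cutoff_band",
]

#: number of interior dual points tolerated before a fit is marked degenerate
_ZERO_RESID_TOL = 1e-8


class QuantileError(ValueError):
    pass


class SingularDesignError(QuantileError):
    pass


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise QuantileError(f"tau must lie in (0, 1), got {tau}")


def pinball_loss(residuals, tau: float) -> float:
    """Total check loss sum_u u*(tau - 1[u<0]); zero iff all residuals zero."""
    _check_tau(tau)
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0.0))))


def design_matrix(records: pd.DataFrame, spec: MetricSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, y) with an intercept column followed by the spec covariates."""
    for col in spec.covariates + (spec.name,):
        if col not in records.columns:
            raise QuantileError(f"missing column {col!r} for metric {spec.name}")
        if records[col].isna().any():
            bad = records.index[records[col].isna()].tolist()[:5]
            raise QuantileError(f"missing values in {col!r} (rows {bad})")
    n = len(records)
    X = np.column_stack(
        [np.ones(n)] + [records[c].to_numpy(dtype=float) for c in spec.covariates]
    )
    y = records[spec.name].to_numpy(dtype=float)
    return X, y


@dataclass
class QuantileFit:
    """One fitted QRL: named coefficients, achieved loss, sample size."""

    metric: str
    tau: float
    coefficients: dict[str, float]  # "intercept" then covariates, in order
    loss: float
    n: int
    spec: MetricSpec
    degenerate: bool = False  # multiple optima possible (extra zero residuals)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(list(self.coefficients.values()))

    def predict(self, age, disc_area=None) -> np.ndarray:
        """Evaluate the cutoff line at the given covariates."""
        out = self.coefficients["intercept"] + 0.0 * np.asarray(age, dtype=float)
        for cov in self.spec.covariates:
            if cov == "age":
                out = out + self.coefficients["age"] * np.asarray(age, dtype=float)
            elif cov == "disc_area":
                if disc_area is None:
                    raise QuantileError(
                        f"metric {self.metric} requires disc_area for evaluation"
                    )
                out = out + self.coefficients["disc_area"] * np.asarray(disc_area, dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "tau": self.tau,
            "coefficients": self.coefficients,
            "loss": self.loss,
            "n": self.n,
            "method": "quantile",
            "degenerate": self.degenerate,
        }


def _solve_quantile_lp(X: np.ndarray, y: np.ndarray, tau: float):
    """Exact LP solve; returns (beta, dual vector d, loss)."""
    n, p = X.shape
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(p),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
    )
    if res.status != 0:
        raise QuantileError(f"quantile LP failed: {res.message}")
    beta = -np.asarray(res.eqlin.marginals, dtype=float)
    loss = pinball_loss(y - X @ beta, tau)
    dual_obj = float(y @ res.x)
    # strong duality check; on rare degenerate bases re-derive beta from the
    # interpolated (interior-dual) observations, which have zero residuals
    if not np.isclose(loss, dual_obj, rtol=1e-7, atol=1e-6):
        d = res.x
        interior = np.flatnonzero((d > tau - 1.0 + 1e-9) & (d < tau - 1e-9))
        if interior.size == p and np.linalg.matrix_rank(X[interior]) == p:
            beta_alt = np.linalg.solve(X[interior], y[interior])
            loss_alt = pinball_loss(y - X @ beta_alt, tau)
            if loss_alt < loss:
                beta, loss = beta_alt, loss_alt
    return beta, np.asarray(res.x, dtype=float), loss


def fit_qrl(records: pd.DataFrame, spec: MetricSpec, tau: float) -> QuantileFit:
    """Fit the tau-th QRL for one metric; deterministic for fixed input."""
    _check_tau(tau)
    X, y = design_matrix(records, spec)
    n, p = X.shape
    if n <= p:
        raise QuantileError(f"need n > {p} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            f"design for {spec.name} is rank deficient (p={p}); "
            "check for constant covariates"
        )
    beta, _, loss = _solve_quantile_lp(X, y, tau)
    resid = y - X @ beta
    names = ("intercept",) + spec.covariates
    return QuantileFit(
        metric=spec.name,
        tau=tau,
        coefficients={k: float(b) for k, b in zip(names, beta)},
        loss=loss,
        n=n,
        spec=spec,
        degenerate=int(np.sum(np.abs(resid) < _ZERO_RESID_TOL)) > p,
    )


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class CoefficientCI:
    """Per-coefficient confidence intervals for one QRL."""

    metric: str
    tau: float
    level: float
    method: str  # "rank_inversion" | "bootstrap"
    point: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    replicates: dict[str, np.ndarray] | None = None  # bootstrap draws per coef
    notes: list[str] = field(default_factory=list)


def _rankscore_statistic(X, y, j: int, b0: float, tau: float) -> float:
    """GJK rank-score z-statistic for H0: beta_j = b0 (sign score at tau).

    The restricted tau-QRL of y - x_j*b0 on the remaining columns yields the
    dual vector d in [tau-1, tau]; the centred rank scores are exactly d and
    the statistic is the score of x_j residualised on the restricted design.
    """
    ytil = y - X[:, j] * b0
    Z = np.delete(X, j, axis=1)
    _, d, _ = _solve_quantile_lp(Z, ytil, tau)
    xj = X[:, j]
    # residualise x_j on Z (least squares projection)
    coef, *_ = np.linalg.lstsq(Z, xj, rcond=None)
    xstar = xj - Z @ coef
    s2 = tau * (1.0 - tau) * float(xstar @ xstar)
    if s2 <= 0:
        raise SingularDesignError("tested covariate is collinear with the rest")
    return float(xstar @ d) / np.sqrt(s2)


def _invert_one_side(X, y, j, bhat, tau, zcrit, direction, scale, tol):
    """Bisection for the CI endpoint in the given direction (+1 upper/-1 lower)."""
    step = scale
    inside = bhat
    # expand until the rank test rejects
    for _ in range(60):
        cand = bhat + direction * step
        if abs(_rankscore_statistic(X, y, j, cand, tau)) > zcrit:
            break
        inside = cand
        step *= 2.0
    else:
        warnings.warn("rank-inversion endpoint search did not bracket; returning last")
        return inside
    outside = bhat + direction * step
    while abs(outside - inside) > tol:
        mid = 0.5 * (inside + outside)
        if abs(_rankscore_statistic(X, y, j, mid, tau)) > zcrit:
            outside = mid
        else:
            inside = mid
    return 0.5 * (inside + outside)


def coefficient_ci(
    records: pd.DataFrame,
    spec: MetricSpec,
    tau: float,
    level: float = 0.95,
    method: str = "rank_inversion",
    n_boot: int = 1000,
    seed: int | None = None,
    large_n_threshold: int = 1000,
) -> CoefficientCI:
    """Confidence intervals for every QRL coefficient at the given level."""
    if method not in ("rank_inversion", "bootstrap"):
        raise QuantileError(f"unsupported CI method {method!r}")
    fit = fit_qrl(records, spec, tau)
    X, y = design_matrix(records, spec)
    names = ("intercept",) + spec.covariates
    notes: list[str] = []
    if method == "rank_inversion":
        if fit.n >= large_n_threshold:
            msg = (
                f"rank inversion requested at n={fit.n} >= {large_n_threshold}; "
                "the method is designed for smaller samples"
            )
            warnings.warn(msg)
            notes.append(msg)
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        intervals = {}
        resid_scale = max(np.std(y - X @ fit.beta), 1e-6)
        for j, name in enumerate(names):
            covar_scale = max(np.std(X[:, j]), 1.0) if j > 0 else 1.0
            scale = resid_scale / covar_scale / np.sqrt(fit.n)
            tol = scale * 1e-3
            lo = _invert_one_side(X, y, j, fit.beta[j], tau, zcrit, -1.0, scale, tol)
            hi = _invert_one_side(X, y, j, fit.beta[j], tau, zcrit, +1.0, scale, tol)
            intervals[name] = (float(lo), float(hi))
        return CoefficientCI(
            spec.name, tau, level, method, dict(fit.coefficients), intervals,
            notes=notes,
        )
    # bootstrap: case resampling, percentile rule
    if n_boot < 100:
        raise QuantileError(f"bootstrap needs >= 100 replicates, got {n_boot}")
    rng = np.random.default_rng(seed)
    n = len(records)
    draws = {name: np.empty(n_boot) for name in names}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < X.shape[1]:
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
        beta_b, _, _ = _solve_quantile_lp(Xb, yb, tau)
        for k, name in enumerate(names):
            draws[name][b] = beta_b[k]
    alpha = 1.0 - level
    intervals = {
        name: (
            float(np.quantile(v, alpha / 2.0)),
            float(np.quantile(v, 1.0 - alpha / 2.0)),
        )
        for name, v in draws.items()
    }
    return CoefficientCI(
        spec.name, tau, level, "bootstrap", dict(fit.coefficients), intervals,
        replicates=draws, notes=notes,
    )


def cutoff_band(
    fit: QuantileFit,
    ci: CoefficientCI,
    age_grid,
    disc_ref: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (lower, upper) band on the cutoff line over an age grid.

    For a bootstrap CI the band is the percentile envelope of the replicate
    cutoff evaluations at each age; for rank inversion it is the interval-
    arithmetic envelope of the per-coefficient intervals.  cpRNFL metrics are
    evaluated at ``disc_ref``.  The band always contains the point cutoff.
    """
    if ci.metric != fit.metric or ci.tau != fit.tau:
        raise QuantileError(
            f"cutoff_band: fit ({fit.metric}, tau={fit.tau}) does not match "
            f"ci ({ci.metric}, tau={ci.tau})"
        )
    ages = np.asarray(age_grid, dtype=float)
    values = {"intercept": 1.0, "age": ages}
    if "disc_area" in fit.spec.covariates:
        values["disc_area"] = disc_ref
    if ci.replicates is not None:
        reps = np.zeros((len(next(iter(ci.replicates.values()))), ages.size))
        for name in ("intercept",) + fit.spec.covariates:
            reps = reps + np.outer(ci.replicates[name], np.ones(ages.size)) * values[name]
        alpha = 1.0 - ci.level
        lower = np.quantile(reps, alpha / 2.0, axis=0)
        upper = np.quantile(reps, 1.0 - alpha / 2.0, axis=0)
    else:
        lower = np.zeros(ages.size)
        upper = np.zeros(ages.size)
        for name in ("intercept",) + fit.spec.covariates:
            lo, hi = ci.intervals[name]
            v = values[name] * np.ones(ages.size) if np.isscalar(values[name]) else values[name]
            lower = lower + np.minimum(lo * v, hi * v)
            upper = upper + np.maximum(lo * v, hi * v)
    point = fit.predict(ages, disc_area=disc_ref)
    return np.minimum(lower, point), np.maximum(upper, point)
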