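"""Constant-variance Gaussian null model for percentile cutoffs.

Under this null, a metric at every age is normally distributed around the
least-squares mean line with one residual SD common to all ages, so the
tau-th percentile cutoff is the mean line shifted by z_tau * sigma — a family
of parallel lines.  Comparing fitted quantile regression lines against these
predictions isolates how far the data depart from the constant-variance
Gaussian assumption (and, at small n, from sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantile import QuantileFit, SingularDesignError, design_matrix, _check_tau
from .registry import MetricSpec

__all__ = ["GaussianModel", "fit_gaussian_model", "gaussian_cutoff", "qrl_gaussian_divergence"]


@dataclass
class GaussianModel:
    """Least-squares mean line plus a single residual SD."""

    metric: str
    coefficients: dict[str, float]  # intercept then covariates
    residual_sd: float
    n: int
    spec: MetricSpec

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(list(self.coefficients.values()))

    def mean(self, age, disc_area=None) -> np.ndarray:
        out = self.coefficients["intercept"] + 0.0 * np.asarray(age, dtype=float)
        for cov in self.spec.covariates:
            if cov == "age":
                out = out + self.coefficients["age"] * np.asarray(age, dtype=float)
            elif cov == "disc_area":
                if disc_area is None:
                    raise ValueError(f"metric {self.metric} requires disc_area")
                out = out + self.coefficients["disc_area"] * np.asarray(disc_area, dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "coefficients": self.coefficients,
            "residual_sd": self.residual_sd,
            "n": self.n,
            "method": "gaussian",
        }


def fit_gaussian_model(records: pd.DataFrame, spec: MetricSpec) -> GaussianModel:
    """OLS mean line with sigma-hat on the unbiased (n - p) denominator."""
    X, y = design_matrix(records, spec)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(f"design for {spec.name} is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = float(np.sqrt(resid @ resid / (n - p)))
    names = ("intercept",) + spec.covariates
    return GaussianModel(
        metric=spec.name,
        coefficients={k: float(b) for k, b in zip(names, beta)},
        residual_sd=sigma,
        n=n,
        spec=spec,
    )


def gaussian_cutoff(model: GaussianModel, tau: float, age, disc_area=None) -> np.ndarray:
    """Predicted tau-percentile cutoff: mean line + z_tau * sigma-hat."""
    _check_tau(tau)
    z = stats.norm.ppf(tau)
    return model.mean(age, disc_area) + z * model.residual_sd


def gaussian_cutoff_fit(model: GaussianModel, tau: float) -> QuantileFit:
    """The Gaussian cutoff line repackaged as a cutoff-line object (the mean
    line's slopes with the intercept shifted by z_tau * sigma-hat), so flagging
    code can treat both methods uniformly."""
    _check_tau(tau)
    coef = dict(model.coefficients)
    coef["intercept"] = float(coef["intercept"] + stats.norm.ppf(tau) * model.residual_sd)
    return QuantileFit(
        metric=model.metric, tau=tau, coefficients=coef, loss=float("nan"),
        n=model.n, spec=model.spec,
    )


def qrl_gaussian_divergence(
    qr_fits: dict[float, QuantileFit],
    model: GaussianModel,
    age_grid,
    disc_ref: float = 2.0,
) -> dict[float, dict]:
    """Per tau: max |QRL - Gaussian prediction| over the age grid (um, at
    disc_ref for cpRNFL metrics) plus per-coefficient differences."""
    ages = np.asarray(age_grid, dtype=float)
    out: dict[float, dict] = {}
    for tau, fit in qr_fits.items():
        if fit.metric != model.metric:
            raise ValueError(
                f"divergence: QR fit metric {fit.metric} != model metric {model.metric}"
            )
        kwargs = {"disc_area": disc_ref} if "disc_area" in fit.spec.covariates else {}
        qr_line = fit.predict(ages, **kwargs)
        gauss_line = gaussian_cutoff(model, tau, ages, **kwargs)
        gfit = gaussian_cutoff_fit(model, tau)
        out[tau] = {
            "max_abs_gap": float(np.max(np.abs(qr_line - gauss_line))),
            "coefficient_gap": {
                k: float(fit.coefficients[k] - gfit.coefficients[k])
                for k in fit.coefficients
            },
        }
    return out
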