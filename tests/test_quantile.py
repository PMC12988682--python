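"""Quantile-regression fitter: exactness, invariance, and CI behaviour."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octnorm import coefficient_ci, cutoff_band, fit_qrl, pinball_loss
from octnorm.quantile import QuantileError, SingularDesignError, design_matrix
from octnorm.registry import METRICS

from _oracles import pinball as oracle_pinball, vertex_enumeration_qr
from conftest import make_cohort, toy_frame


@pytest.mark.parametrize(
    "u,tau,expected",
    [(2.0, 0.05, 0.10), (-2.0, 0.05, 1.90), (0.0, 0.3, 0.0), ([1.0, -1.0], 0.5, 1.0)],
)
def test_pinball_examples(u, tau, expected):
    assert pinball_loss(np.atleast_1d(u), tau) == pytest.approx(expected)


@pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
def test_pinball_tau_domain(tau):
    with pytest.raises(QuantileError):
        pinball_loss([1.0], tau)


@pytest.mark.parametrize("tau", [0.5, 0.05, 0.01])
def test_constant_data_perfect_fit(gcl_spec, tau):
    df = toy_frame([20, 35, 50, 65, 80], [70.0] * 5)
    fit = fit_qrl(df, gcl_spec, tau)
    assert fit.coefficients["intercept"] == pytest.approx(70.0, abs=1e-8)
    assert fit.coefficients["age"] == pytest.approx(0.0, abs=1e-10)
    assert fit.loss == pytest.approx(0.0, abs=1e-9)


def test_toy_median_matches_vertex_oracle(gcl_spec):
    """Five-point median regression agrees with exhaustive enumeration of
    all candidate lines through point pairs."""
    df = toy_frame([20, 30, 40, 50, 60], [100, 96, 97, 90, 88])
    X, y = design_matrix(df, gcl_spec)
    oracle_loss, oracle_beta = vertex_enumeration_qr(X, y, 0.5)
    fit = fit_qrl(df, gcl_spec, 0.5)
    assert fit.loss == pytest.approx(oracle_loss, rel=1e-9, abs=1e-12)
    np.testing.assert_allclose(fit.beta, oracle_beta, rtol=1e-7)


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("tau", [0.5, 0.2, 0.05])
def test_small_instances_match_vertex_oracle(seed, tau):
    """On every random instance with n <= 12 the LP loss equals the
    brute-force vertex-enumeration minimum."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    use_disc = bool(seed % 2)
    spec = METRICS["g_cpRNFL" if use_disc else "g_GCLplus"]
    ages = rng.uniform(18, 90, n)
    disc = rng.uniform(1.0, 3.2, n)
    y = 100 - 0.3 * ages + rng.normal(0, 8, n)
    df = toy_frame(ages, y, metric=spec.name, disc=disc)
    X, yv = design_matrix(df, spec)
    oracle_loss, _ = vertex_enumeration_qr(X, yv, tau)
    fit = fit_qrl(df, spec, tau)
    assert fit.loss == pytest.approx(oracle_loss, rel=1e-9, abs=1e-9)


@given(
    seed=st.integers(0, 10_000),
    tau=st.sampled_from([0.5, 0.05, 0.01, 0.9]),
    n=st.integers(30, 200),
)
@settings(max_examples=25, deadline=None)
def test_in_sample_quantile_property(seed, tau, n):
    """#{r < 0} <= n*tau and #{r <= 0} >= n*tau - p at the optimum."""
    rng = np.random.default_rng(seed)
    spec = METRICS["g_GCLplus"]
    ages = rng.uniform(18, 90, n)
    y = 75 - 0.1 * ages + rng.normal(0, 6, n)
    fit = fit_qrl(toy_frame(ages, y), spec, tau)
    X, yv = design_matrix(toy_frame(ages, y), spec)
    r = yv - X @ fit.beta
    p = spec.n_coefficients
    assert np.sum(r < -1e-9) <= n * tau + 1e-9
    assert np.sum(r <= 1e-9) >= n * tau - p - 1e-9


def test_shift_and_scale_equivariance(gcl_spec):
    rng = np.random.default_rng(3)
    ages = rng.uniform(18, 90, 80)
    y = 75 - 0.1 * ages + rng.normal(0, 6, 80)
    fit = fit_qrl(toy_frame(ages, y), gcl_spec, 0.05)
    shifted = fit_qrl(toy_frame(ages, y + 7.5), gcl_spec, 0.05)
    assert shifted.coefficients["intercept"] == pytest.approx(
        fit.coefficients["intercept"] + 7.5, abs=1e-6
    )
    assert shifted.coefficients["age"] == pytest.approx(
        fit.coefficients["age"], abs=1e-8
    )
    scaled = fit_qrl(toy_frame(ages * 2.0, y), gcl_spec, 0.05)
    assert scaled.coefficients["age"] == pytest.approx(
        fit.coefficients["age"] / 2.0, abs=1e-8
    )


def test_statsmodels_crosscheck(rw_like, cp_spec):
    """Achieved loss is no worse than statsmodels QuantReg's on the same data."""
    statsmodels = pytest.importorskip("statsmodels.api")
    _, df = rw_like
    X, y = design_matrix(df, cp_spec)
    for tau in (0.05, 0.5):
        fit = fit_qrl(df, cp_spec, tau)
        sm_fit = statsmodels.QuantReg(y, X).fit(q=tau)
        sm_loss = oracle_pinball(y - X @ sm_fit.params, tau)
        assert fit.loss <= sm_loss + 1e-6
        np.testing.assert_allclose(fit.beta, sm_fit.params, rtol=2e-3, atol=2e-2)


def test_cutoffs_ordered_across_taus(rw_like, gcl_spec):
    _, df = rw_like
    fits = {t: fit_qrl(df, gcl_spec, t) for t in (0.01, 0.05, 0.5)}
    ages = np.asarray(df["age"])
    c1 = fits[0.01].predict(ages)
    c5 = fits[0.05].predict(ages)
    c50 = fits[0.5].predict(ages)
    assert np.all(c1 <= c5 + 1e-9) and np.all(c5 <= c50 + 1e-9)


def test_singular_design_raises(gcl_spec):
    df = toy_frame([50.0] * 20, np.random.default_rng(0).normal(70, 5, 20))
    with pytest.raises(SingularDesignError):
        fit_qrl(df, gcl_spec, 0.05)


def test_missing_covariate_raises(cp_spec):
    df = toy_frame([30, 40, 50, 60], [100, 98, 96, 94], metric="g_cpRNFL")
    df = df.drop(columns=["disc_area"])
    with pytest.raises(QuantileError, match="disc_area"):
        fit_qrl(df, cp_spec, 0.05)


# ---------------------------------------------------------------------------
# confidence intervals and bands
# ---------------------------------------------------------------------------

def test_bootstrap_ci_collapses_on_noise_free_data(gcl_spec):
    ages = np.linspace(20, 80, 40)
    df = toy_frame(ages, 80 - 0.2 * ages)
    ci = coefficient_ci(df, gcl_spec, 0.05, method="bootstrap", n_boot=150, seed=0)
    for lo, hi in ci.intervals.values():
        assert hi - lo < 1e-8


def test_rank_inversion_ci_narrow_on_near_noise_free_data(gcl_spec):
    rng = np.random.default_rng(1)
    ages = np.linspace(20, 80, 60)
    df = toy_frame(ages, 80 - 0.2 * ages + rng.normal(0, 1e-4, 60))
    ci = coefficient_ci(df, gcl_spec, 0.5, method="rank_inversion")
    lo, hi = ci.intervals["age"]
    assert hi - lo < 1e-3
    assert lo <= ci.point["age"] <= hi


def test_ci_methods_agree_and_cover(small_rdb, gcl_spec):
    """Rank-inversion and bootstrap intervals overlap and both contain the
    generating slope on a well-behaved cohort."""
    cfg, df = small_rdb
    truth = cfg.metric_models["g_GCLplus"].beta_age
    ri = coefficient_ci(df, gcl_spec, 0.05, method="rank_inversion")
    bs = coefficient_ci(df, gcl_spec, 0.05, method="bootstrap", n_boot=300, seed=5)
    for name in ri.intervals:
        lo1, hi1 = ri.intervals[name]
        lo2, hi2 = bs.intervals[name]
        assert max(lo1, lo2) <= min(hi1, hi2), f"{name} intervals disjoint"
    assert ri.intervals["age"][0] <= truth <= ri.intervals["age"][1]
    assert bs.intervals["age"][0] <= truth <= bs.intervals["age"][1]


def test_ci_bad_method_and_small_B(small_rdb, gcl_spec):
    _, df = small_rdb
    with pytest.raises(QuantileError):
        coefficient_ci(df, METRICS["g_GCLplus"], 0.05, method="jackknife")
    with pytest.raises(QuantileError):
        coefficient_ci(df, METRICS["g_GCLplus"], 0.05, method="bootstrap", n_boot=50)


def test_rank_inversion_warns_at_large_n(rw_like, gcl_spec):
    _, df = rw_like
    with pytest.warns(UserWarning, match="rank inversion"):
        coefficient_ci(df, gcl_spec, 0.5, method="rank_inversion", large_n_threshold=1000)


def test_cutoff_band_zero_width_equals_line(small_rdb, gcl_spec):
    _, df = small_rdb
    fit = fit_qrl(df, gcl_spec, 0.05)
    ci = coefficient_ci(df, gcl_spec, 0.05, method="rank_inversion")
    degenerate = dataclasses.replace(
        ci, intervals={k: (v, v) for k, v in ci.point.items()}
    )
    ages = np.linspace(20, 80, 13)
    lo, hi = cutoff_band(fit, degenerate, ages)
    np.testing.assert_allclose(lo, fit.predict(ages), atol=1e-9)
    np.testing.assert_allclose(hi, fit.predict(ages), atol=1e-9)


def test_cutoff_band_monotone_in_interval_width(small_rdb, cp_spec):
    _, df = small_rdb
    fit = fit_qrl(df, cp_spec, 0.05)
    ci = coefficient_ci(df, cp_spec, 0.05, method="rank_inversion")
    ages = np.linspace(20, 80, 25)
    lo, hi = cutoff_band(fit, ci, ages, disc_ref=2.0)
    assert np.all(lo <= fit.predict(ages, disc_area=2.0) + 1e-9)
    assert np.all(hi >= fit.predict(ages, disc_area=2.0) - 1e-9)
    wider = dataclasses.replace(
        ci,
        intervals={
            k: (v[0] - 0.1 * (v[1] - v[0]), v[1] + 0.1 * (v[1] - v[0]))
            for k, v in ci.intervals.items()
        },
    )
    lo_w, hi_w = cutoff_band(fit, wider, ages, disc_ref=2.0)
    assert np.all(lo_w <= lo + 1e-12) and np.all(hi_w >= hi - 1e-12)


def test_bootstrap_band_matches_percentile_oracle(small_rdb, gcl_spec):
    """The band from bootstrap replicates equals per-age percentiles of the
    replicate cutoff evaluations computed directly in the test."""
    _, df = small_rdb
    fit = fit_qrl(df, gcl_spec, 0.05)
    ci = coefficient_ci(df, gcl_spec, 0.05, method="bootstrap", n_boot=400, seed=2)
    ages = np.array([40.0, 60.0])
    lo, hi = cutoff_band(fit, ci, ages)
    reps = ci.replicates
    for k, age in enumerate(ages):
        vals = reps["intercept"] + reps["age"] * age
        assert lo[k] <= np.quantile(vals, 0.025) + 1e-9
        assert hi[k] >= np.quantile(vals, 0.975) - 1e-9
        # band beyond the raw percentile only where needed to hold the point fit
        assert lo[k] == pytest.approx(
            min(np.quantile(vals, 0.025), fit.predict(age)), abs=1e-9
        )
        assert hi[k] == pytest.approx(
            max(np.quantile(vals, 0.975), fit.predict(age)), abs=1e-9
        )


def test_cutoff_band_mismatch_raises(small_rdb, gcl_spec, cp_spec):
    _, df = small_rdb
    fit5 = fit_qrl(df, gcl_spec, 0.05)
    ci1 = coefficient_ci(df, gcl_spec, 0.01, method="rank_inversion")
    with pytest.raises(QuantileError, match="does not match"):
        cutoff_band(fit5, ci1, np.linspace(20, 80, 5))
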