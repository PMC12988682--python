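# Methods

`octnorm` studies how the choice of a normative ("reference") database
changes the clinical flagging of OCT retinal-layer thickness metrics, and
whether the change is explained by sampling error alone. This note records
the models, the calibrated defaults, the numerical choices, and the limits
of what the synthetic experiments demonstrate.

## The flagging model

A reference database (RDB) is a cohort of healthy eyes. For each of 24
thickness metrics (17 circumpapillary RNFL metrics: global, 4 quadrants, 12
clock hours; 7 macular GCL+ metrics: global and 6 sectors) the package fits
quantile regression lines (QRLs) at the 50th, 5th and 1st percentiles:

    Q_tau(thickness | age, disc area) = b0(tau) + b_age(tau)*age [+ b_disc(tau)*disc_area]

cpRNFL-family metrics include disc area as a covariate; GCL+ metrics use age
only (matching the covariate sets commercial instruments apply to these
metric families). A test eye is flagged **yellow** if its value falls
strictly below the 5th-percentile cutoff at its own covariates, **red** if
strictly below the 1st, otherwise **green**. Values exactly on a cutoff are
not "below" it; ties have probability zero for continuous data, and the
convention resolves them toward the less abnormal colour.

### Quantile fitting

The tau-th QRL minimises the pinball loss `sum_i rho_tau(y_i - x_i'b)`,
solved exactly as a linear program in dual form (n bounded variables, p
equality constraints) with the HiGHS solver. The equality-constraint
multipliers are the primal coefficients; the dual vector doubles as the
regression rank scores. The dual LP is orders of magnitude faster than the
naive primal at n ~ 10^5 and is deterministic for fixed input. When the
solver lands on a degenerate basis (more than p zero residuals), the fit is
flagged `degenerate`; coefficients are then one of several optima, chosen by
the solver's deterministic pivot order.

Quantile crossing (the 1st-percentile line above the 5th at some covariate
point) is not repaired. `classify_eye`/`flag_cohort` raise on crossing by
default; the study pipeline instead passes `on_crossing="log"`, which
classifies the affected eyes against the sorted pair of cutoffs and records
their ids in the run report. Crossing almost always occurs at covariate
extremes of small (~400-eye) databases, where the 1st-percentile fit rests
on a handful of observations — exactly the pathology the analysis is about,
so it is surfaced, never silently repaired.

### Confidence intervals

Two per-coefficient interval methods at level 0.95 (pointwise, per
coefficient; no simultaneity claim):

* **Rank inversion** — the regression rank-score test with the sign (tau)
  score function, holding the other coefficients at their point estimates,
  inverted by bisection to the set of parameter values the level-alpha test
  does not reject. Intended for n below ~1000; above that a warning is
  recorded. Simulation at n = 398, tau = 0.05 puts the empirical coverage
  of the age-slope interval near 92-94%, the familiar slight undercoverage
  of marginal rank-score inversion at tail quantiles.
* **Bootstrap** — case resampling with B >= 100 replicates and the
  percentile rule; replicates are retained so cutoff *bands* over an age
  grid can be read off per-age percentiles. For rank-inversion CIs the band
  is the interval-arithmetic envelope of the coefficient intervals
  (conservative, monotone under interval widening).

### The Gaussian null

The null model assumes thickness at every age is Gaussian around the
least-squares mean line with a single residual SD (denominator n - p), so
percentile cutoffs are parallel lines `mean + z_tau * sigma`. The null uses
the same covariate set as the QR model for the metric; applying identical
designs is the only comparison that isolates the distributional assumption.
`qrl_gaussian_divergence` reports the maximum vertical gap over an age grid
and per-coefficient differences. On homoscedastic Gaussian data the QRLs
converge to these lines (verified at n = 100,000 to < 0.5 um over ages
20-80); on heteroscedastic data the lower-percentile QRLs tilt away, which
the variance-drift parameter of the generator (below) can reproduce.

### Monte Carlo subsampling

To ask whether a small database behaves like a random draw from the large
one: repeatedly (default 1000 iterations) sample m = 398 eyes without
replacement from the large database, refit the 5th/1st percentile QRLs,
collect each coefficient's empirical distribution, and form 95% intervals
from the 2.5th/97.5th percentiles (linear interpolation between order
statistics at position (k-1)/(n-1)). Membership of the small database's
coefficients uses closed interval endpoints. Singular subsamples (measure
zero with continuous ages) are re-drawn up to 10 times, then abort. With
m = n every iteration reproduces the full-cohort fit and the intervals are
exactly degenerate. The subsample mean of a tail-quantile slope carries a
small finite-m attenuation relative to the full-cohort fit; it is visible
only when m is a large fraction below n and the source is small, and is
acknowledged in the tests rather than corrected.

### Comparison metrics

The 3x3 transition table of flag colours (same eyes, two RDBs) is the
complete bookkeeping object; the four row categories of the published-style
tables (G->Y, Y->G, Y->R, R->Y) are projections of it, and the G->R / R->G
cells are also reported because nothing rules them out when cutoff lines
are far apart. At the 5% level a "positive" is yellow-or-red; at 1% it is
red. Signed changes in TP (disease cohort) and FP (healthy cohort) follow
from the transition cells; delta-sensitivity, delta-specificity and
delta-accuracy are these counts over the relevant cohort sizes, times 100.
Two accuracy conventions are emitted — (dTP + dTN)/N and dTP/N — because
published per-level accuracy deltas are not always computable under one
convention. Percentages are formatted half-up to one decimal; raw fractions
are also available. The screening projection rounds `pop * prevalence` to
whole cases and `cases * delta_sensitivity` to whole individuals.

## The synthetic-data generator

No eye-level data are distributed, so the generator is a first-class module
that emulates the study's four cohorts:

| cohort           | n    | age (mean +/- SD, range)   | calibration anchors      |
|------------------|------|----------------------------|--------------------------|
| reference_large  | 4830 | 48.6 +/- 17.0, 18-90       | g-cpRNFL 103.3 +/- 10.9 um, g-GCL+ 71.1 +/- 5.8 um |
| reference_small  | 398  | 46.2 +/- 16.3, 18-88       | same population model    |
| healthy_test     | 175  | 49.3 +/- 15.0, 22-86       | same population model    |
| disease_test     | 183  | 68.5 +/- 7.5, 60-92        | g-cpRNFL 81.0 um, g-GCL+ 61.3 um |

Ages and disc areas (normal, mean 2.0 mm^2, SD 0.4, truncated at 0.8; the
source study prints no disc-area marginals) are drawn by rejection sampling
from truncated normals — exact, and cheap because the truncation windows
are wide. Each metric is linear in age (and disc area for cpRNFL metrics)
plus Gaussian noise `sigma(age) = sigma0 * (1 + gamma*(age-50))`; gamma
defaults to 0 (the Gaussian null's constant-variance world) and is the dial
for breaking that assumption in experiments. Age slopes are not published;
the defaults (-0.2 um/yr for cpRNFL, -0.1 for GCL+) are configurable and no
acceptance property depends on their values. Intercepts and residual SDs
are solved per metric so the *marginal* mean/SD under the reference age and
disc distributions (truncated-normal moments computed analytically) hit the
anchors above; local metrics use typical normative magnitudes since only
the global marginals are published. All four cohorts share one population
model — the hypothesis under test is precisely that the two RDBs sample one
population.

Disease is a per-eye thickness deficit, truncated-normal at zero
(SD 12.5 um), subtracted from every metric and clipped at a 20 um floor
(residual glial tissue). The deficit mean is solved so the post-loss
g-cpRNFL marginal hits 81.0 um; the GCL+ family receives a calibrated
fraction (~0.43) of each eye's deficit so g-GCL+ lands at 61.3 um, since a
single shared deficit cannot match both published means. This produces a
severity spectrum from subtle to advanced loss; it does **not** model the
spatial geometry of arcuate defects, inter-eye correlation, or the true
(unknown) severity distribution of the clinical cohort. Consequently,
passing tests show that the *statistical machinery* reproduces the
published arithmetic and the sample-size phenomenology on a population with
the published marginals — not that the generator reproduces the clinical
cohorts themselves.

One eye per subject throughout; every cohort draws from its own named,
seeded generator, and seeds are recorded in run manifests. The full study
derives per-stage seeds from a single master seed in a fixed order.

## Problem sizes and numerical choices

* Vertex-enumeration oracle equality is asserted on random instances with
  n <= 12 (where enumeration is exhaustive), loss agreement to 1e-9
  relative.
* Gaussian-limit recovery uses n = 100,000 (one LP solve ~1-3 s).
* Coverage simulation: 500 cohorts of n = 398 in the test suite, 300 in the
  acceptance script.
* Subsampling membership: 22 local metrics x 2 taus, 200 iterations of
  m = 398 from n = 4830 — CI endpoints differ from the 1000-iteration run
  by O(1/iterations), immaterial to the inside/outside counts checked.
* Rank-inversion bisection tolerance: 1e-3 of a data-scaled step; CI
  endpoint search expands geometrically from the point estimate before
  bisecting.
* Strong duality is checked on every LP solve (loss vs dual objective,
  rtol 1e-7); on the rare degenerate bases coefficients are re-derived from
  the interior-dual (zero-residual) rows.

## Known limitations

* The rank-score inversion is marginal (one coefficient at a time, others
  fixed at point estimates) — slightly anticonservative at tail quantiles;
  the joint-inversion variant is out of scope.
* Cutoff bands are pointwise, not simultaneous.
* Quantile crossing inside the data range is logged, never repaired; the
  "log" classification of crossed eyes (sorted cutoffs) is a reporting
  convenience, not a statistical fix.
* The generator's Gaussian noise makes the Gaussian null exactly true at
  gamma = 0; real thickness distributions are mildly skewed and
  heteroscedastic, so real-data divergences will exceed the synthetic ones.
* No race/ethnicity, axial-length or fovea-disc-distance covariates; no
  bilateral eyes.
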