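# octnorm

Age-conditional normative limits for OCT retinal-layer thickness metrics,
and a complete analysis of how clinical flagging changes when a small
normative ("reference") database is replaced by a much larger one.

OCT glaucoma reports flag a summary metric — e.g. global circumpapillary
RNFL thickness (g-cpRNFL) or global ganglion cell + inner plexiform layer
thickness (g-GCL+) — **yellow** when it falls below the 5th percentile of a
healthy reference database (RDB) at the patient's age, and **red** below the
1st percentile. Commercial RDBs are small (~300-850 eyes), so those tail
cutoffs are noisy. This package asks, quantitatively: if a 398-eye RDB is
replaced by a 4830-eye real-world RDB drawn from the same population, which
eyes change colour, what happens to sensitivity and specificity, and is the
disagreement explained by sampling error alone?

## What it computes

For each metric, the tau-th quantile regression line (QRL)

    Q_tau(y | age, disc) = b0(tau) + b_age(tau) * age [+ b_disc(tau) * disc_area]

is fitted at tau = 0.50, 0.05, 0.01 by exact minimisation of the pinball
loss `sum_i rho_tau(y_i - x_i'b)` (dual-form linear program; disc area enters
for the 17 cpRNFL metrics, age only for the 7 GCL+ metrics), with 95%
confidence intervals by rank-score test inversion or case bootstrap. Around
it:

* a constant-variance **Gaussian null** (`mean line + z_tau * sigma`) against
  which QRL departures are measured;
* a **flag engine** applying the strict-below rule at each eye's covariates;
* **comparison metrics**: 3x3 flag-transition tables between two RDBs,
  delta-sensitivity/specificity/accuracy at the 5% and 1% levels, flag
  discordance ("accuracy of flagging"), and a screening-population
  projection;
* **Monte Carlo subsampling**: 1000 draws of 398 eyes (without replacement)
  from the large RDB, refitting the QRLs each time, with percentile 95% CIs
  of every coefficient and membership checks of the small RDB's
  coefficients;
* a calibrated **synthetic-cohort generator** emulating the four study
  cohorts (no eye-level data are distributed).

## Worked example

```bash
python analysis/01_simulate_cohorts.py --seed 0
python analysis/04_flag_and_compare.py
```

prints (seed 0):

```
reference_large  n= 4830  age  49.6  g-cpRNFL  103.4 +/- 10.9 um  g-GCL+  71.0 +/-  5.7 um
reference_small  n=  398  age  45.6  g-cpRNFL  104.0 +/- 11.0 um  g-GCL+  71.0 +/-  5.9 um
healthy_test     n=  175  age  50.0  g-cpRNFL  102.2 +/- 10.5 um  g-GCL+  71.5 +/-  5.7 um
disease_test     n=  183  age  70.4  g-cpRNFL   82.8 +/- 15.0 um  g-GCL+  61.5 +/-  7.4 um
...
g_cpRNFL: disease flags changed 11/183 (6.0%), healthy 0/175 (0.0%)
  delta sensitivity 5%: -1.1%  1%: +4.9%   screening: ~2 extra cases per 1000 screened
```

Both reference databases are drawn from one population, yet 6% of diseased
eyes change colour while essentially no healthy eyes do — the small
database's tail cutoffs, not the population, drive the disagreement.
`analysis/02_fit_quantile_lines.py` shows the mechanism (the 398-eye
database's 1st-percentile age slope is wildly uncertain),
`analysis/03_gaussian_null.py` shows its 1st-percentile QRL deviating
~3.5-4 um from the Gaussian null while the 4830-eye database stays within
~1 um, and `analysis/05_monte_carlo_subsampling.py` shows the small
database's coefficients landing inside the 95% subsampling intervals — a
plausible 398-eye draw.

The same steps are available as a CLI (`octnorm simulate|fit|flag|compare|mc|study`);
`octnorm study --seed 0 --out results/study` runs everything end to end with
a manifest of per-stage seeds. See `docs/methods.md` for the models,
calibration and numerical choices.

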