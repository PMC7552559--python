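# telomr

One-sample **linear and non-linear Mendelian randomization (MR)** for a
continuous ln-scale exposure — leukocyte telomere length (ln TL) — on a binary
outcome — ischemic stroke — from individual-level case-control data.

Observational studies disagree on whether short telomeres cause stroke.
MR sidesteps confounding and reverse causation by using telomere-length
SNPs as instrumental variables: a variant that lowers TL from birth should
raise stroke risk if (and only if) short TL is causal.  Because two-sample MR
assumes a (log-)linear exposure-outcome relationship, a U-shaped or threshold
effect needs the one-sample, individual-level design this package implements.
It is written for epidemiologists and biostatisticians running that design:
genotype QC and instrument validation, the linear estimators, the
semiparametric non-linear machinery, and a synthetic cohort generator for
method evaluation when the real data cannot be shared.

## The model

With instruments G_j, exposure X = ln TL, covariates C and a binary outcome Y:

    logit P(Y = 1 | X, C) = alpha + f(X) + gamma' C

* **Instrument validation** — MAF >= 0.05, control-group Hardy-Weinberg
  equilibrium (exact test), control-only exposure association under the
  over-dominant genetic model (heterozygote vs both homozygotes; additive,
  dominant, recessive and co-dominant available), and a pleiotropy screen of
  the genotype against every measured covariate.
* **Linear MR** — per-instrument Wald ratios theta_j = beta_y_j / beta_x_j
  (exposure stage in controls, covariate-adjusted logistic outcome stage in
  everyone) combined by the inverse-variance weighted (IVW) method, maximum
  likelihood (ML), and the mode-based estimate (MBE).  Results are reported
  as theta and as the OR per 10% TL decrease, exp(theta ln 0.9).
* **Non-linear MR** — subjects stratified on the *IV-free exposure* (the
  residual of X on the genetic risk score), a localized average causal effect
  (LACE) per stratum, and three tests of a flat LACE profile: the quadratic
  (trend) test, Cochran's Q, and the degree-1 fractional polynomial test;
  plus piecewise-linear and fractional-polynomial causal curves.
* **Observational companions** — descriptive "Table 1" with the t /
  Mann-Whitney / chi-squared convention, adjusted logistic exposure-outcome
  OR, and an exposure-quintile case-control comparison.

See `docs/methods.md` for the full statistical account.

## Worked example

The two instruments of the bundled study panel have published control-group
effects on ln TL of -0.108 and -0.089 (heterozygote vs homozygotes; about a
10.2% and 8.5% shorter telomere) and over-dominant stroke ORs of 0.810 and
0.890.  Combining those summary statistics:

```python
from telomr import datasets
from telomr.linear import all_linear_estimates, estimates_frame

summary = datasets.study_summary_associations()
print(estimates_frame(all_linear_estimates(summary, n_boot=1000, seed=1))
      .round(3).to_string(index=False))
```

```
method  theta    se  ci_low  ci_high  or_per_10pct_decrease  or_ci_low  or_ci_high  n_instruments
   ivw  1.657 1.144  -0.585    3.899                  0.840      0.663       1.064              2
    ml  1.670 1.280  -0.839    4.179                  0.839      0.644       1.092              2
   mbe  1.746 1.171  -0.578    3.958                  0.832      0.659       1.063              2
```

Reading the IVW row: the crude (unadjusted) combination of the two ratio
estimates gives theta = 1.66 log-odds per unit ln TL with a CI spanning zero —
equivalently an OR of 0.84 (0.66-1.06) per 10% TL decrease — i.e. no evidence
of a causal effect from the unadjusted summary statistics alone, and wide
uncertainty, as two instruments at this sample size must give.  (Covariate
adjustment, which requires the individual-level data, moves such estimates
substantially; these crude numbers are a worked example, not a replication.)

End-to-end on a synthetic cohort, from a shell:

```bash
telomr run-all --config examples/study_scale.yaml --seed 2 --out run2/
```

writes one TSV per stage (genotype distributions, instrument QC with
exclusion reasons, summary associations, the three linear MR estimates, LACE
strata, the three non-linearity tests, causal curves, descriptives,
quintiles) plus a run log recording the seed and every exclusion.  At this
sample size (304 controls, published instrument p-values of 0.026 and 0.049,
fourteen screened covariates at raw alpha = 0.05) instrument selection is
itself noisy: some seeds select both instruments, others fewer, and the MR
stages are then skipped with the reason logged — a realistic property of the
design, not a bug.

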