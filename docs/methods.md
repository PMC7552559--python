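# Methods

`telomr` implements a one-sample Mendelian randomization (MR) analysis of a
continuous ln-scale exposure (leukocyte telomere length, ln TL in ln kb) on a
binary outcome (ischemic stroke) from individual-level case-control data,
together with a synthetic cohort generator that reproduces the statistical
structure the analysis assumes.

## The causal model and estimands

Genetic variants G_j serve as instruments for the exposure X = ln TL under the
three instrumental-variable assumptions: each G_j is associated with X, is
independent of confounders, and affects the outcome Y only through X.  The
outcome model is logistic,

    logit P(Y = 1 | X, C) = alpha + f(X) + gamma' C,

and the analysis asks whether f is zero, linear (f(x) = theta x), or
non-linear.  All effects are reported both as theta (log-odds per unit ln TL)
and as the odds ratio per 10% decrease in TL.  A 10% decrease multiplies TL by
0.9 and shifts ln TL by ln 0.9, so OR = exp(theta ln 0.9); this convention is
configurable (`div_1.1` interprets the decrease as division by 1.1).

### Genetic models

The principal contrast is over-dominant (heterosis): heterozygotes versus both
homozygote classes pooled, coded 1/0.  Additive (allele count), dominant,
recessive and co-dominant (two indicator contrasts against the reference
homozygote) codings are available for subsidiary analyses.  Effect-allele
orientation defaults to the alternate allele and can be flipped per SNP; the
over-dominant coding is orientation-free.

### Instrument validation

Candidates are filtered in a fixed order, each exclusion recording its first
failed rule: (1) control-group minor allele frequency >= 0.05; (2) control
group consistent with Hardy-Weinberg equilibrium (exact test by default,
p >= 0.05); (3) genotype-exposure association among controls significant at
0.05 (least squares of ln TL on the coded genotype, unadjusted by default —
whether the source analysis adjusted its exposure stage is not knowable, so
adjustment is optional and recorded); (4) no association with any screened
covariate at 0.05 (continuous covariates by least squares; binary covariates
as a mean difference on the 0/1 coding by default, with a logistic log-odds
alternative).  No multiplicity correction is applied anywhere, matching
conventional practice in this design.  A consequence worth knowing: with 14
screened covariates at raw alpha = 0.05, a perfectly valid instrument clears
the whole screen only about 0.95^14 ≈ 49% of the time, so at small sample
sizes the selected-instrument count is itself noisy.

The exact Hardy-Weinberg test enumerates the conditional distribution of the
heterozygote count given the allele counts via the standard recurrence
(rescaled in-flight to avoid overflow far from the mode) and sums the
probabilities not exceeding the observed one; the chi-squared 1-df
goodness-of-fit test is the alternative.  Odds ratios from 2x2 tables use the
cross-product ratio with Woolf (log-OR) confidence intervals and a flagged 0.5
continuity correction when a cell is zero — back-computation of the bundled
study tables matches the published two-decimal ORs and CIs under exactly this
recipe.

## Linear MR

Per-instrument summary statistics are computed on the same cohort: beta_x
(exposure stage) in controls only, since case status can distort the
genotype-exposure relationship; beta_y (outcome stage) by covariate-adjusted
logistic regression on the full sample.  Three estimators combine the Wald
ratios theta_j = beta_y_j / beta_x_j:

* **IVW** — fixed-effect inverse-variance weighted mean with first-order
  delta-method SEs (se_y/|beta_x|; a second-order option adds the
  exposure-stage term).  Algebraically the zero-intercept weighted regression
  of beta_y on beta_x.
* **Maximum likelihood** — maximizes the joint Gaussian likelihood
  beta_x_j ~ N(xi_j, se_x_j^2), beta_y_j ~ N(theta xi_j, se_y_j^2).  The
  nuisance means are profiled out in closed form; theta is optimized
  numerically from the IVW start, the SE comes from the observed information
  of the full parameterization, and non-convergence is flagged rather than
  silently replaced.
* **Mode-based estimate (MBE)** — the mode of an inverse-variance-weighted
  normal-kernel density of the ratio estimates.  Bandwidth is a modified
  Silverman rule, 0.9 min(sd, 1.4826 MAD) J^(-1/5), times a configurable
  factor (default 1).  The mode is located on a coarse grid refined to 1e-4
  resolution; the CI is a seeded parametric bootstrap (default 1000 draws,
  theta_j* ~ N(theta_j, se_j), bandwidth recomputed per draw, percentile
  interval).  With fewer than three instruments the mode is statistically
  degenerate; it is computed and flagged.

A two-stage (GRS first stage, logistic second stage) cross-check is provided
as a diagnostic only; its SE ignores first-stage uncertainty.

## Non-linear MR

The semiparametric stage stratifies on the **IV-free exposure**: the residual
of ln TL after removing the genetic risk score's contribution (fit in
controls by default, applied to all subjects), so strata do not condition on a
collider.  The GRS is the unweighted count of exposure-lowering risk
genotypes (here: heterozygotes of the selected instruments).  Within each of
K strata (default K = 5, quintiles; configurable 2-10) the localized average
causal effect is LACE_k = beta_y_k / beta_x_k from within-stratum GRS
regressions, with the two-stage delta-method SE.  Degenerate strata (constant
GRS, single outcome class, separation) are flagged and dropped with the test
degrees of freedom reduced.

Three tests compare the LACE profile with the flat profile a linear f implies:

* **Quadratic test** — weighted least-squares trend of LACE_k on the stratum
  exposure means (a quadratic f makes its derivative, hence LACE, linear in x).
* **Cochran's Q** — heterogeneity of LACE_k around the weighted mean,
  chi-squared on K-1 df.
* **Fractional polynomial test** — the degree-1 fractional polynomial causal
  curve c x^p with p in {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (p = 0 is the
  logarithm) has derivative c g_p(x), g_p(x) = x^(p-1); each power is fitted
  to the LACE profile by weighted Gaussian likelihood, and twice the
  log-likelihood gain of the best power over the linear reference (p = 1) is
  referred to chi-squared 1 df.  Power-selection multiplicity is ignored, as
  in the reference implementation of this test, which makes it mildly
  anti-conservative; the measured type-I error at the default study
  conditions is about 4% (see calibration below).  Exposures are already
  ln-scale and positive in real data; if any stratum mean is non-positive
  (possible in centered simulations) a shift of 1 - min is applied and
  recorded.

Causal curves are reconstructed relative to a reference exposure (default:
the mean): piecewise-linearly, integrating each stratum's constant LACE slope
across segments whose interior boundaries are midpoints between consecutive
stratum exposure means (stratum exposure *ranges* overlap once strata come
from residuals, so they cannot serve as boundaries directly), with pointwise
variance accumulating the independent stratum variances; and parametrically
from the fitted fractional polynomial, h(x) = c (G_p(x) - G_p(ref)) with G_p
the antiderivative of g_p and a delta-method band on c.

## Observational analyses

"Table 1"-style descriptives select mean ± SD with Welch's t test when both
groups pass Shapiro-Wilk at 0.05, otherwise median (IQR, linear-interpolation
quartiles) with the tie-corrected asymptotic Mann-Whitney U; categorical
variables get n (%) per level and a Pearson chi-squared test.  The
observational exposure-outcome OR comes from covariate-adjusted logistic
regression.  The quintile comparison cuts the pooled exposure into fifths and
compares case versus control exposure within each, emitting box-plot-ready
summaries (whiskers at 1.5 IQR clipped to the data).

## The synthetic cohort generator

The generator emulates the study design rather than any particular dataset:

* **Genotypes** — independent biallelic SNPs in Hardy-Weinberg proportions
  (two Bernoulli allele draws per subject).  No linkage disequilibrium and no
  population structure, matching the analysis' treatment of instruments as
  independent.
* **Exposure** — ln TL = mean + sum of per-SNP effects (over-dominant by
  default: delta_j per heterozygote; additive available) + covariate effects
  + Gaussian noise.
* **Covariates** — continuous Normal(mean, sd) or binary Bernoulli(prev),
  independent by default with an optional correlation matrix applied to the
  latent Gaussians (Cholesky).  Effects on exposure and outcome act on the
  mean-centered covariate, so the baseline log-odds is the log-odds at
  covariate means — a package choice that keeps study-scale configurations
  feasible for rejection sampling.
* **Outcome** — logistic with linear predictor baseline + f(ln TL) +
  covariate effects, where f is null, linear (theta x), quadratic
  (theta x + theta2 x^2) or threshold (theta max(0, x - c)) — the minimal
  shapes that distinguish the three non-linearity tests.
* **Case-control sampling** — rejection sampling from the population model
  until exactly n_cases and n_controls accumulate (cap 10^7 draws), which
  preserves the population genotype-exposure joint distribution among
  controls — the property the control-only exposure stage relies on.  Same
  seed, same cohort, bit for bit.

The study-scale default (`default_study_config`) draws 431 cases / 304
controls, the twelve-SNP candidate panel at the observed control allele
frequencies (four of them below the 0.05 MAF filter), over-dominant exposure
effects of -0.108 and -0.089 ln-kb on the two instruments, exposure
ln TL ~ 1.9 ± 0.35 (about 6.7 kb), and a covariate block (age, sex, smoking,
drinking, BMI, blood pressures, glucose, lipids, apolipoproteins) whose
marginals loosely match the study population.  The covariate generator
targets those marginals only loosely: it does not reproduce the real
covariate dependence structure, case-control covariate imbalance beyond the
modeled outcome effects, or measurement error in TL, so passing tests show
the *estimators* behave correctly under the assumed model, not that any
specific published estimate is reproduced.

`calibration_config` is the stripped-down variant used in the Monte Carlo
studies: centered exposure (mean 0, sd 1), four strong instruments
(MAF 0.3, delta = -0.3), no covariates.

## Calibration experiments and problem sizes

The experiments module runs the studies the test suite and acceptance script
report, each reproducible from one integer seed (child seeds from a
`SeedSequence`, all below 2^31):

* exposure-stage recovery of delta = -0.10 (100 replicates, n = 5000);
* IVW/ML recovery of theta = 0.25 under a linear f (100 replicates,
  n = 20000).  theta = 0.25 keeps the logistic non-collapsibility bias
  (~0.17 theta^3 sigma^2, here < 0.003) well inside Monte-Carlo noise;
* 95% CI coverage of IVW/ML at theta = 0 (500 summary-level replicates,
  10 instruments);
* type-I error of the three non-linearity tests under linear f (K = 5,
  n = 5000, 200 replicates; measured ~2.5-5% per test);
* power of the quadratic test under quadratic f with theta2 = 0.15
  (n = 20000, 50 replicates).  theta2 was fixed a priori: the induced LACE
  trend slope is 2 theta2, and the analytic weighted-least-squares slope SE
  at these conditions is ~0.05, putting the design z-score near 6 and power
  essentially at 1, comfortably above the 80% design point.

## Numerical choices and edge cases

* Two-sided p-values and alpha = 0.05 throughout; CIs are effect ± 1.96 se.
* Logistic fits use Newton iterations at tolerance 1e-10; quasi-separation
  (divergent coefficients or perfect-prediction warnings) raises a structured
  error rather than returning a divergent estimate.
* A constant response in the exposure regression returns effect 0, p = 1 (a
  valid degenerate input); a constant genotype code or collinear design
  raises a singular-design error.
* Monomorphic SNPs have HWE p defined as 1 with a warning flag; SEs recovered
  from published CIs use (high - low)/3.92.
* Stratification ties are broken by stable subject order; stratum sizes
  differ by at most one.
* Scores from incomplete genotypes are missing unless an observed-fraction
  threshold is met (default: require completeness).

## Known limitations

* One-sample MR with overlapping exposure and outcome samples inherits
  weak-instrument bias toward the observational association; only first-stage
  strength reporting is provided, not a weak-instrument-robust estimator.
* The MBE with two instruments (the study's situation) is statistically
  degenerate; it is computed with a warning because the design calls for it.
* The fractional polynomial test's power selection is unpenalized
  (anti-conservative by construction, conservative in practice at these
  conditions).
* No doubly-ranked stratification, no individual-level spline MR, no
  two-sample estimators (MR-Egger, weighted median) — out of scope for this
  design.
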