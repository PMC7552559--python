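"""Synthetic case-control cohorts with the structure the MR pipeline assumes.

The generator emulates a one-sample telomere-length / ischemic-stroke study:
biallelic SNPs drawn under Hardy-Weinberg equilibrium, a ln-scale exposure
with small over-dominant genotype effects, correlated demographic and
biochemical covariates, and a logistic outcome whose dependence on the
exposure is configurable (null, linear, quadratic, or threshold).  Cases and
controls are accumulated by rejection sampling from the population model until
the requested case/control counts are reached, which keeps the
genotype-exposure joint distribution in controls faithful to the population
(the control-only instrument estimation relies on that).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, SNPRecord

CAUSAL_SHAPES = ("null", "linear", "quadratic", "threshold")


@dataclass(frozen=True)
class SNPSpec:
    """One simulated SNP: allele frequency and its effect on ln-exposure.

    ``delta`` is the mean ln-exposure difference of the risk genotype versus
    the reference coding (heterozygote versus both homozygotes under the
    default over-dominant effect model).
    """

    snp_id: str
    maf: float
    delta: float = 0.0
    chromosome: str = "1"
    gene: Optional[str] = None
    ref_allele: str = "C"
    alt_allele: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.snp_id}: MAF must be in [0, 1], got {self.maf}")

    def record(self, position: Optional[int] = None) -> SNPRecord:
        return SNPRecord(self.snp_id, self.chromosome, self.gene,
                         self.ref_allele, self.alt_allele, position)


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate and its effects.

    Continuous covariates are Normal(mean, sd); binary ones Bernoulli(prevalence).
    ``beta_exposure`` and ``beta_outcome`` act on the *mean-centered* covariate
    (centered at the mean, or at the prevalence for binary variables), so
    ``baseline_log_odds`` is the log-odds at covariate means.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    beta_exposure: float = 0.0
    beta_outcome: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.kind == "binary" and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence must be in [0, 1]")

    @property
    def center(self) -> float:
        return self.mean if self.kind == "continuous" else self.prevalence


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of one synthetic case-control study."""

    n_cases: int
    n_controls: int
    snps: tuple[SNPSpec, ...]
    exposure_mean: float = 1.9  # ln kb
    exposure_sd: float = 0.35
    covariates: tuple[CovariateSpec, ...] = ()
    causal_shape: str = "null"
    theta: float = 0.0  # log-odds per unit ln-exposure (linear term)
    theta2: float = 0.0  # quadratic term
    threshold: float = 0.0  # knot of the threshold shape
    baseline_log_odds: float = 0.0
    seed: int = 0
    genetic_effect_model: str = "over-dominant"
    covariate_corr: Optional[np.ndarray] = None
    max_draws: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be positive")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if self.causal_shape not in CAUSAL_SHAPES:
            raise ValueError(f"causal_shape must be one of {CAUSAL_SHAPES}")
        for v in (self.theta, self.theta2, self.threshold, self.baseline_log_odds):
            if not math.isfinite(v):
                raise ValueError("causal-shape parameters must be finite")
        if self.genetic_effect_model not in ("over-dominant", "additive"):
            raise ValueError("genetic_effect_model must be 'over-dominant' or 'additive'")
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.covariate_corr is not None:
            c = np.asarray(self.covariate_corr, dtype=float)
            p = len(self.covariates)
            if c.shape != (p, p):
                raise ValueError("covariate_corr must be square, one row per covariate")
            np.linalg.cholesky(c)  # must be positive definite

    def causal_effect(self, exposure: np.ndarray) -> np.ndarray:
        """f(ln TL): the exposure's contribution to the outcome linear predictor."""
        x = np.asarray(exposure, dtype=float)
        if self.causal_shape == "null":
            return np.zeros_like(x)
        if self.causal_shape == "linear":
            return self.theta * x
        if self.causal_shape == "quadratic":
            return self.theta * x + self.theta2 * x**2
        return self.theta * np.maximum(0.0, x - self.threshold)


def simulate_genotypes(maf_list, n_subjects: int, seed) -> pd.DataFrame:
    """Independent biallelic genotypes under HWE.

    ``maf_list`` is a mapping snp_id -> allele frequency or a sequence of
    frequencies (ids are generated).  Each SNP's allele-count genotype is
    drawn with probabilities ((1-q)^2, 2q(1-q), q^2).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if isinstance(maf_list, dict):
        items = list(maf_list.items())
    else:
        items = [(f"snp{i + 1}", q) for i, q in enumerate(maf_list)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = {}
    for snp_id, q in items:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"{snp_id}: MAF must be in [0, 1], got {q}")
        # two independent allele draws per subject <=> HWE genotype frequencies
        data[snp_id] = rng.binomial(2, q, size=n_subjects).astype(float)
    return pd.DataFrame(data)


def _draw_covariates(config: SimulationConfig, n: int, rng) -> pd.DataFrame:
    specs = config.covariates
    if not specs:
        return pd.DataFrame(index=range(n))
    z = rng.standard_normal((n, len(specs)))
    if config.covariate_corr is not None:
        z = z @ np.linalg.cholesky(np.asarray(config.covariate_corr, float)).T
    cols = {}
    for j, spec in enumerate(specs):
        if spec.kind == "continuous":
            cols[spec.name] = spec.mean + spec.sd * z[:, j]
        else:
            cols[spec.name] = (z[:, j] < norm.ppf(spec.prevalence)).astype(float)
    return pd.DataFrame(cols)


def _genetic_exposure_effect(config: SimulationConfig, genotypes: pd.DataFrame) -> np.ndarray:
    from .genetics import encode_genotype

    model = config.genetic_effect_model
    effect = np.zeros(len(genotypes))
    for spec in config.snps:
        if spec.delta != 0.0:
            effect += spec.delta * encode_genotype(genotypes[spec.snp_id].to_numpy(), model)
    return effect


def _draw_population(config: SimulationConfig, n: int, rng):
    genotypes = simulate_genotypes({s.snp_id: s.maf for s in config.snps}, n, rng)
    covariates = _draw_covariates(config, n, rng)
    exposure = (
        config.exposure_mean
        + _genetic_exposure_effect(config, genotypes)
        + rng.normal(0.0, config.exposure_sd, size=n)
    )
    for spec in config.covariates:
        if spec.beta_exposure != 0.0:
            exposure += spec.beta_exposure * (covariates[spec.name].to_numpy() - spec.center)
    lp = config.baseline_log_odds + config.causal_effect(exposure)
    for spec in config.covariates:
        if spec.beta_outcome != 0.0:
            lp += spec.beta_outcome * (covariates[spec.name].to_numpy() - spec.center)
    outcome = rng.random(n) < expit(lp)
    return genotypes, covariates, exposure, outcome.astype(int)


_BATCH = 8192


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a case-control cohort with exactly the configured case/control counts.

    Population draws are accepted into the case or control arm until both
    quotas fill; a cap of ``config.max_draws`` guards against infeasible
    configurations (case probability near 0 or 1).  Reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    need_cases, need_controls = config.n_cases, config.n_controls
    kept: list[tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]] = []
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= config.max_draws:
            raise RuntimeError(
                f"case-control sampling infeasible: {drawn} draws still leave "
                f"{need_cases} cases / {need_controls} controls unfilled"
            )
        n = min(_BATCH, config.max_draws - drawn)
        drawn += n
        g, c, x, y = _draw_population(config, n, rng)
        take = np.zeros(n, dtype=bool)
        case_idx = np.flatnonzero(y == 1)[:need_cases]
        ctrl_idx = np.flatnonzero(y == 0)[:need_controls]
        take[case_idx] = True
        take[ctrl_idx] = True
        need_cases -= len(case_idx)
        need_controls -= len(ctrl_idx)
        kept.append((g.loc[take], c.loc[take], x[take], y[take]))

    genotypes = pd.concat([k[0] for k in kept], ignore_index=True)
    covariates = pd.concat([k[1] for k in kept], ignore_index=True)
    exposure = np.concatenate([k[2] for k in kept])
    outcome = np.concatenate([k[3] for k in kept])
    ids = pd.Index([f"S{i + 1:05d}" for i in range(len(outcome))], name="subject_id")
    phenotypes = pd.DataFrame({"outcome": outcome, "exposure": exposure}, index=ids)
    for col in covariates.columns:
        phenotypes[col] = covariates[col].to_numpy()
    genotypes.index = ids
    records = {s.snp_id: s.record(position=(i + 1) * 1000)
               for i, s in enumerate(config.snps)}
    return Cohort(
        phenotypes,
        genotypes,
        snps=records,
        meta={"seed": config.seed, "draws_used": drawn, "config": config},
    )


# ---------------------------------------------------------------------------
# Ready-made configurations


def default_study_config(seed: int = 0, causal_shape: str = "null",
                         theta: float = 0.0, theta2: float = 0.0) -> SimulationConfig:
    """The study-scale default: 431 cases / 304 controls, a 12-SNP candidate
    panel with the observed control allele frequencies (four below the 0.05
    MAF filter), over-dominant exposure effects of about -0.11 and -0.09 ln-kb
    on the two true instruments, exposure ~ ln kb around 1.9 (about 6.7 kb),
    and the full demographic/biochemical covariate block with marginals loosely
    matching the study population."""
    snps = (
        SNPSpec("rs11125529", 0.1842, delta=-0.108, chromosome="2", gene="ACYP2",
                ref_allele="C", alt_allele="A"),
        SNPSpec("rs6772228", 0.000, chromosome="3", ref_allele="T", alt_allele="A"),
        SNPSpec("rs10936599", 0.4178, chromosome="3", gene="MYNN",
                ref_allele="T", alt_allele="C"),
        SNPSpec("rs7726159", 0.3832, chromosome="5", gene="TERT",
                ref_allele="C", alt_allele="A"),
        SNPSpec("rs9420907", 0.006, chromosome="10", ref_allele="C", alt_allele="A"),
        SNPSpec("rs17653722", 0.1513, chromosome="12", gene="KRT80",
                ref_allele="G", alt_allele="T"),
        SNPSpec("rs3027234", 0.042, chromosome="17", ref_allele="C", alt_allele="T"),
        SNPSpec("rs8105767", 0.2714, chromosome="19", ref_allele="A", alt_allele="G"),
        SNPSpec("rs409627", 0.3372, chromosome="19", gene="ZNF676",
                ref_allele="G", alt_allele="C"),
        SNPSpec("rs412658", 0.3372, delta=-0.089, chromosome="19", gene="ZNF676",
                ref_allele="C", alt_allele="T"),
        SNPSpec("rs6028466", 0.002, chromosome="20", ref_allele="A", alt_allele="T"),
        SNPSpec("rs755017", 0.4227, chromosome="20", gene="ZBTB46",
                ref_allele="A", alt_allele="G"),
    )
    covariates = (
        CovariateSpec("age", "continuous", mean=53.0, sd=14.0,
                      beta_exposure=-0.002, beta_outcome=0.06),
        CovariateSpec("sex_male", "binary", prevalence=0.51, beta_outcome=0.55),
        CovariateSpec("smoking", "binary", prevalence=0.32, beta_outcome=0.9),
        CovariateSpec("drinking", "binary", prevalence=0.36, beta_outcome=0.4),
        CovariateSpec("bmi", "continuous", mean=25.0, sd=3.3, beta_outcome=0.05),
        CovariateSpec("sbp", "continuous", mean=131.0, sd=16.0, beta_outcome=0.03),
        CovariateSpec("dbp", "continuous", mean=81.0, sd=11.0, beta_outcome=0.01),
        CovariateSpec("fpg", "continuous", mean=5.3, sd=1.1, beta_outcome=0.10),
        CovariateSpec("tg", "continuous", mean=1.5, sd=0.8, beta_outcome=0.10),
        CovariateSpec("tc", "continuous", mean=4.4, sd=0.8, beta_outcome=-0.15),
        CovariateSpec("hdl", "continuous", mean=1.15, sd=0.25, beta_outcome=-1.0),
        CovariateSpec("ldl", "continuous", mean=2.5, sd=0.7, beta_outcome=0.05),
        CovariateSpec("apoa1", "continuous", mean=1.22, sd=0.16, beta_outcome=-0.8),
        CovariateSpec("apob", "continuous", mean=0.95, sd=0.25, beta_outcome=-0.4),
    )
    return SimulationConfig(
        n_cases=431,
        n_controls=304,
        snps=snps,
        exposure_mean=1.9,
        exposure_sd=0.35,
        covariates=covariates,
        causal_shape=causal_shape,
        theta=theta,
        theta2=theta2,
        baseline_log_odds=math.log(431 / 304),
        seed=seed,
    )


def calibration_config(
    n_cases: int,
    n_controls: int,
    causal_shape: str = "linear",
    theta: float = 0.0,
    theta2: float = 0.0,
    n_snps: int = 4,
    maf: float = 0.3,
    delta: float = -0.3,
    exposure_sd: float = 1.0,
    seed: int = 0,
) -> SimulationConfig:
    """A stripped-down configuration for estimator calibration experiments:
    strong instruments, centered exposure, no covariates.  Used by the
    parameter-recovery, coverage and non-linearity calibration studies."""
    snps = tuple(SNPSpec(f"iv{j + 1}", maf, delta=delta) for j in range(n_snps))
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        snps=snps,
        exposure_mean=0.0,
        exposure_sd=exposure_sd,
        causal_shape=causal_shape,
        theta=theta,
        theta2=theta2,
        baseline_log_odds=0.0,
        seed=seed,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
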