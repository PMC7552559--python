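"""Genotype encodings, allele frequencies, Hardy-Weinberg tests and 2x2 odds ratios.

Genotypes arrive as alternate-allele counts (0/1/2, NaN missing).  Five genetic
models are supported; the principal analysis model is over-dominant (heterosis:
heterozygote versus both homozygote classes), with additive, dominant,
recessive and co-dominant contrasts available for subsidiary analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENETIC_MODELS = ("additive", "dominant", "recessive", "co-dominant", "over-dominant")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Three-category genotype counts for one group (e.g. controls)."""

    hom_ref: int
    het: int
    hom_alt: int

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    def as_array(self) -> np.ndarray:
        return np.array([self.hom_ref, self.het, self.hom_alt], dtype=float)

    @classmethod
    def from_genotypes(cls, genotypes) -> "GenotypeCounts":
        g = np.asarray(genotypes, dtype=float)
        g = g[~np.isnan(g)]
        return cls(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


def encode_genotype(genotypes, model: str, effect_allele: str = "alt") -> np.ndarray:
    """Numerically code allele-count genotypes under a genetic model.

    Parameters
    ----------
    genotypes
        Array-like of {0, 1, 2, NaN} alternate-allele counts.
    model
        One of :data:`GENETIC_MODELS`.  ``over-dominant`` codes heterozygotes 1
        and either homozygote 0; ``co-dominant`` returns two indicator columns
        (het, hom-effect) with the non-effect homozygote as reference.
    effect_allele
        ``"alt"`` (default) or ``"ref"``; with ``"ref"`` the allele count is
        flipped to 2 - g before coding.

    Missing genotypes propagate as NaN.
    """
    g = np.asarray(genotypes, dtype=float)
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("genotypes must be allele counts in {0,1,2} or NaN")
    if effect_allele == "ref":
        g = 2.0 - g
    elif effect_allele != "alt":
        raise ValueError(f"effect_allele must be 'alt' or 'ref', got {effect_allele!r}")

    nan = np.isnan(g)
    if model == "additive":
        code = g.copy()
    elif model == "dominant":
        code = (g >= 1).astype(float)
    elif model == "recessive":
        code = (g == 2).astype(float)
    elif model == "over-dominant":
        code = (g == 1).astype(float)
    elif model == "co-dominant":
        code = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        code[nan, :] = np.nan
        return code
    else:
        raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")
    code[nan] = np.nan
    return code


def compute_maf(counts: GenotypeCounts) -> float:
    """Minor allele frequency min(q, 1-q), q = (het + 2 hom_alt) / (2 n)."""
    if counts.total == 0:
        raise ValueError("cannot compute MAF from an empty group")
    q = (counts.het + 2 * counts.hom_alt) / (2 * counts.total)
    return min(q, 1.0 - q)


@dataclass(frozen=True)
class HWEResult:
    statistic: Optional[float]
    p_value: float
    method: str
    monomorphic: bool = False


def hwe_test(counts: GenotypeCounts, method: str = "exact") -> HWEResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``method="chi2"`` is the 1-df goodness-of-fit test of observed versus
    expected counts at the sample allele frequency.  ``method="exact"`` is the
    conditional exact test: the sum of probabilities of all heterozygote counts
    (given allele counts) whose probability does not exceed the observed one.
    A monomorphic SNP has nothing to test: p is defined as 1 with a warning.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty genotype counts")
    n_alt = counts.het + 2 * counts.hom_alt
    if n_alt == 0 or n_alt == 2 * n:
        warnings.warn("monomorphic SNP: HWE p defined as 1", stacklevel=2)
        return HWEResult(0.0 if method == "chi2" else None, 1.0, method, monomorphic=True)

    if method == "chi2":
        q = n_alt / (2 * n)
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
        observed = counts.as_array()
        stat = float(((observed - expected) ** 2 / expected).sum())
        return HWEResult(stat, float(stats.chi2.sf(stat, df=1)), "chi2")
    if method == "exact":
        p = _hwe_exact_p(counts.het, counts.hom_ref, counts.hom_alt)
        return HWEResult(None, p, "exact")
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact HWE p-value via the standard heterozygote-count recurrence.

    Probabilities of all heterozygote counts compatible with the observed
    allele counts are built from the conditional distribution
    P(het | n, n_rare); the p-value sums those <= the observed probability.
    """
    n = n_het + n_hom_ref + n_hom_alt
    rare = min(n_het + 2 * n_hom_ref, n_het + 2 * n_hom_alt)
    # heterozygote counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(het_values))
    # start from the largest feasible het count and recurse downwards:
    # P(h-2)/P(h) = h(h-1) / (4 (nr + 1)(nc + 1)) with nr, nc the homozygote
    # counts at h (rare and common respectively)
    probs[-1] = 1.0
    for i in range(len(het_values) - 1, 0, -1):
        h = het_values[i]
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (n_rare_hom + 1) * (n_common_hom + 1))
        if probs[i - 1] > 1e250:  # rescale to dodge overflow far from the mode
            probs[i - 1 :] /= probs[i - 1]
    probs /= probs.sum()
    observed = probs[het_values.index(n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def genotype_case_control_test(
    counts_cases: GenotypeCounts, counts_controls: GenotypeCounts
) -> tuple[float, int, float]:
    """Pearson chi-squared on the 3x2 genotype-by-status table.

    Genotype categories empty in both groups are dropped (df reduced
    accordingly).  Returns ``(statistic, df, p_value)``.
    """
    table = np.column_stack([counts_cases.as_array(), counts_controls.as_array()])
    table = table[table.sum(axis=1) > 0]
    if table.size == 0 or table.sum() == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2:
        return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]
    log_or: float
    se_log_or: float
    p_value: float
    continuity_corrected: bool = False


def contingency_or(
    exposed_cases: float,
    unexposed_cases: float,
    exposed_controls: float,
    unexposed_controls: float,
) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log-OR) 95% confidence interval.

    A zero cell triggers the 0.5 continuity correction on all four cells and
    is flagged on the result.
    """
    cells = np.array(
        [exposed_cases, unexposed_cases, exposed_controls, unexposed_controls], dtype=float
    )
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt((1.0 / cells).sum())
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci95=(math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)),
        log_or=log_or,
        se_log_or=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        continuity_corrected=corrected,
    )


def build_grs(
    genotypes: pd.DataFrame,
    risk_genotypes: Mapping[str, Iterable[int]],
    min_complete_fraction: float = 1.0,
) -> pd.Series:
    """Unweighted genetic risk score: the count of risk genotypes carried.

    ``risk_genotypes`` maps each SNP id to the set of allele-count codes that
    constitute the risk genotype (here the exposure-lowering heterozygote,
    ``{1}``).  A subject with missing genotypes gets a missing score unless the
    observed fraction of score SNPs reaches ``min_complete_fraction``.
    """
    unknown = [s for s in risk_genotypes if s not in genotypes.columns]
    if unknown:
        raise KeyError(f"risk genotype definition references unknown SNP(s): {unknown}")
    snps = list(risk_genotypes)
    sub = genotypes[snps].to_numpy(dtype=float)
    risk = np.zeros_like(sub)
    for j, snp in enumerate(snps):
        risk[:, j] = np.isin(sub[:, j], list(risk_genotypes[snp])).astype(float)
    missing = np.isnan(sub)
    risk[missing] = 0.0
    complete = 1.0 - missing.mean(axis=1)
    score = risk.sum(axis=1)
    score[complete < min_complete_fraction - 1e-12] = np.nan
    return pd.Series(score, index=genotypes.index, name="grs")


def genotype_labels(record) -> dict[int, str]:
    """Human-readable genotype labels (e.g. {0: 'C/C', 1: 'C/A', 2: 'A/A'})."""
    r, a = record.ref_allele, record.alt_allele
    return {0: f"{r}/{r}", 1: f"{r}/{a}", 2: f"{a}/{a}"}


def genotype_distribution_table(
    snp_ids: Sequence[str],
    counts_cases: Mapping[str, GenotypeCounts],
    counts_controls: Mapping[str, GenotypeCounts],
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Per-SNP genotype distribution report: counts, one-decimal percentages,
    the case-control chi-squared p, and the control-group HWE p."""
    rows = []
    for snp in snp_ids:
        cc, ct = counts_cases[snp], counts_controls[snp]
        _, _, p_cc = genotype_case_control_test(cc, ct)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_hwe = hwe_test(ct, method=hwe_method).p_value
        for gcode, name in enumerate(("hom_ref", "het", "hom_alt")):
            n_case = cc.as_array()[gcode]
            n_ctrl = ct.as_array()[gcode]
            rows.append(
                {
                    "snp_id": snp,
                    "genotype": name,
                    "controls_n": int(n_ctrl),
                    "controls_pct": round(100.0 * n_ctrl / ct.total, 1),
                    "cases_n": int(n_case),
                    "cases_pct": round(100.0 * n_case / cc.total, 1),
                    "p_case_control": p_cc,
                    "p_hwe_controls": p_hwe,
                }
            )
    return pd.DataFrame(rows)
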