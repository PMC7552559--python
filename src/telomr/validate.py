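"""Instrument validation against the three IV assumptions.

A candidate SNP qualifies as an instrument when (1) it is associated with the
exposure (ln telomere length) among controls, (2) it is independent of measured
confounders (the pleiotropy screen), and (3) it passes the frequency and
Hardy-Weinberg filters.  Exposure associations are estimated in controls only,
since case status may distort the genotype-exposure relationship.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._glm import SingularDesignError, logit_term, ols_term
from .cohort import Cohort
from .genetics import Z95, encode_genotype

EXCLUSION_ORDER = ("maf", "hwe", "exposure_association", "pleiotropy")


@dataclass(frozen=True)
class AssociationResult:
    """An estimated effect with its uncertainty.

    ``kind`` distinguishes mean differences on the ln-exposure scale from
    log-odds; ``ci95`` is effect +/- 1.96 se throughout.
    """

    effect: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    model: Optional[str] = None
    adjusted_for: tuple[str, ...] = ()
    kind: str = "mean_difference"
    term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 must be ordered")


def _wald_result(fit, **kw) -> AssociationResult:
    half = Z95 * fit.se
    return AssociationResult(
        effect=fit.coef,
        se=fit.se,
        ci95=(fit.coef - half, fit.coef + half),
        p_value=fit.p_value,
        n_used=fit.n_used,
        **kw,
    )


def exposure_association(
    cohort: Cohort,
    snp: str,
    model: str = "over-dominant",
    covariates: Sequence[str] = (),
    controls_only: bool = True,
    min_complete: int = 10,
) -> AssociationResult:
    """Genotype -> ln-exposure mean difference from a least-squares regression.

    By default unadjusted and restricted to controls; ``covariates`` are added
    to the design when supplied and recorded on the result.
    """
    sub = cohort.controls() if controls_only else cohort
    code = encode_genotype(sub.genotype(snp), model)
    X = [np.atleast_2d(code.T).T]
    for c in covariates:
        X.append(sub.phenotypes[c].to_numpy(dtype=float)[:, None])
    X = np.hstack(X)
    y = sub.exposure.to_numpy(dtype=float)
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if complete.sum() < min_complete:
        raise ValueError(f"only {int(complete.sum())} complete cases (< {min_complete})")
    fit = ols_term(y, X, term=0)
    return _wald_result(
        fit, model=model, adjusted_for=tuple(covariates), kind="mean_difference", term=snp
    )


def percent_difference(beta: float) -> float:
    """Percentage difference in the exposure implied by a ln-scale effect:
    (exp(beta) - 1) * 100."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    return (math.exp(beta) - 1.0) * 100.0


def pleiotropy_screen(
    cohort: Cohort,
    snp: str,
    model: str = "over-dominant",
    covariates: Sequence[str] = (),
    binary_as: str = "mean_difference",
) -> list[AssociationResult]:
    """Genotype -> covariate associations among controls (IV assumption 2).

    Continuous covariates: mean difference by least squares.  Binary
    covariates: by default also a mean difference on the 0/1 coding (the
    forest-plot-compatible scale); set ``binary_as="log_odds"`` for a logistic
    contrast instead.  Constant covariates are flagged and skipped.
    """
    if binary_as not in ("mean_difference", "log_odds"):
        raise ValueError("binary_as must be 'mean_difference' or 'log_odds'")
    sub = cohort.controls()
    code = encode_genotype(sub.genotype(snp), model)
    results: list[AssociationResult] = []
    for cov in covariates:
        y = sub.phenotypes[cov].to_numpy(dtype=float)
        finite = y[np.isfinite(y)]
        if finite.size == 0 or np.ptp(finite) == 0.0:
            warnings.warn(f"covariate {cov!r} is constant among controls; skipped", stacklevel=2)
            continue
        is_binary = set(np.unique(finite)) <= {0.0, 1.0}
        if is_binary and binary_as == "log_odds":
            fit = logit_term(y, code, term=0)
            kind = "log_odds"
        else:
            fit = ols_term(y, code, term=0)
            kind = "mean_difference"
        results.append(_wald_result(fit, model=model, kind=kind, term=cov))
    return results


@dataclass
class InstrumentReport:
    """Everything needed to decide whether one candidate SNP is a valid IV."""

    snp_id: str
    maf: float
    hwe_p: Optional[float]
    exposure_assoc: Optional[AssociationResult]
    covariate_screen: list[AssociationResult] = field(default_factory=list)
    selected: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.selected and self.exclusion_reason is not None:
            raise ValueError("a selected instrument cannot carry an exclusion reason")


def select_instruments(
    candidate_reports: Sequence[InstrumentReport],
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
    exposure_alpha: float = 0.05,
    screen_alpha: float = 0.05,
) -> list[InstrumentReport]:
    """Apply the instrument filters in a fixed order and record the first failure.

    Order: MAF >= ``maf_min``; control-group HWE p >= ``hwe_alpha``; exposure
    association p < ``exposure_alpha`` (a missing association counts as not
    demonstrated); no pleiotropy-screen association below ``screen_alpha``.
    Per-candidate rules only, so the selected set is invariant to candidate
    order.
    """
    if not candidate_reports:
        raise ValueError("empty candidate list")
    out = []
    for rep in candidate_reports:
        reason = None
        if rep.maf < maf_min:
            reason = "maf"
        elif rep.hwe_p is not None and rep.hwe_p < hwe_alpha:
            reason = "hwe"
        elif rep.exposure_assoc is None or not (rep.exposure_assoc.p_value < exposure_alpha):
            reason = "exposure_association"
        elif any(r.p_value < screen_alpha for r in rep.covariate_screen):
            reason = "pleiotropy"
        out.append(replace(rep, selected=reason is None, exclusion_reason=reason))
    return out


def build_instrument_report(
    cohort: Cohort,
    snp: str,
    model: str = "over-dominant",
    screen_covariates: Sequence[str] = (),
    hwe_method: str = "exact",
) -> InstrumentReport:
    """Assemble MAF, control HWE p, exposure association and pleiotropy screen
    for one candidate SNP from individual-level data."""
    from .genetics import GenotypeCounts, compute_maf, hwe_test

    counts = GenotypeCounts.from_genotypes(cohort.controls().genotype(snp))
    maf = compute_maf(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hwe_p = hwe_test(counts, method=hwe_method).p_value
    try:
        assoc = exposure_association(cohort, snp, model=model)
    except (SingularDesignError, ValueError):
        assoc = None
    screen = (
        pleiotropy_screen(cohort, snp, model=model, covariates=screen_covariates)
        if assoc is not None
        else []
    )
    return InstrumentReport(snp, maf, hwe_p, assoc, screen)


def instrument_report_frame(reports: Sequence[InstrumentReport]) -> pd.DataFrame:
    """Flatten instrument reports to the one-row-per-candidate QC table."""
    rows = []
    for r in reports:
        a = r.exposure_assoc
        rows.append(
            {
                "snp_id": r.snp_id,
                "maf": r.maf,
                "hwe_p": r.hwe_p,
                "md": a.effect if a else np.nan,
                "md_low": a.ci95[0] if a else np.nan,
                "md_high": a.ci95[1] if a else np.nan,
                "md_p": a.p_value if a else np.nan,
                "pct_difference": percent_difference(a.effect) if a else np.nan,
                "selected": r.selected,
                "exclusion_reason": r.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows)
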