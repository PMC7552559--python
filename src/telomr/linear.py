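"""Linear one-sample Mendelian randomization from per-instrument summaries.

Each instrument j contributes a genotype->exposure association (beta_x_j,
se_x_j, estimated in controls) and a genotype->outcome log-odds association
(beta_y_j, se_y_j, estimated in the full sample with covariate adjustment).
The causal log-odds of outcome per unit ln-exposure, theta, is estimated by

* inverse-variance weighting (IVW) of the ratio estimates theta_j = by_j/bx_j,
* maximum likelihood over the joint Gaussian model of (bx_j, by_j), and
* the mode-based estimate (MBE): the mode of a weighted kernel density of the
  ratio estimates, with a parametric bootstrap for its confidence interval.

Results are also reported as the odds ratio of the outcome per 10% decrease in
the (untransformed) exposure: a 10% decrease multiplies telomere length by 0.9
and hence shifts ln TL by ln 0.9, so OR = exp(theta * ln 0.9).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._glm import logit_term, ols_term
from .cohort import Cohort
from .genetics import Z95, encode_genotype
from .validate import AssociationResult, _wald_result

LN_09 = math.log(0.9)


@dataclass(frozen=True)
class SummaryAssociations:
    """Per-instrument (beta_x, se_x, beta_y, se_y) summary statistics."""

    snp_ids: tuple[str, ...]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = len(self.snp_ids)
        if n < 1:
            raise ValueError("at least one instrument required")
        if any(a.shape != (n,) for a in arrays.values()):
            raise ValueError("summary arrays must all have one entry per instrument")
        if (arrays["se_x"] <= 0).any() or (arrays["se_y"] <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_ci(cls, snp_ids, beta_x, ci_x, beta_y, ci_y, adjusted_for=()):
        """Recover SEs as (high - low) / (2 * 1.96) when only 95% CIs are given."""
        se = lambda ci: np.array([(hi - lo) / (2 * Z95) for lo, hi in ci])
        return cls(tuple(snp_ids), np.asarray(beta_x, float), se(ci_x),
                   np.asarray(beta_y, float), se(ci_y), tuple(adjusted_for))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "beta_x": self.beta_x, "se_x": self.se_x,
             "beta_y": self.beta_y, "se_y": self.se_y}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, adjusted_for=()):
        return cls(tuple(df["snp_id"]), df["beta_x"].to_numpy(), df["se_x"].to_numpy(),
                   df["beta_y"].to_numpy(), df["se_y"].to_numpy(), tuple(adjusted_for))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds-per-unit-ln-exposure scale."""

    method: str
    theta: float
    se: float
    ci95: tuple[float, float]
    or_per_10pct_decrease: float
    or_ci95: tuple[float, float]
    n_instruments: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 must be ordered")
        if self.or_per_10pct_decrease <= 0:
            raise ValueError("odds ratio must be positive")


def outcome_association(
    cohort: Cohort,
    snp: str,
    model: str = "over-dominant",
    covariates: Sequence[str] = (),
    min_complete: int = 20,
) -> AssociationResult:
    """Genotype -> outcome log-odds from a covariate-adjusted logistic fit."""
    code = encode_genotype(cohort.genotype(snp), model)
    X = [np.atleast_2d(code.T).T]
    for c in covariates:
        X.append(cohort.phenotypes[c].to_numpy(dtype=float)[:, None])
    X = np.hstack(X)
    y = cohort.outcome.to_numpy(dtype=float)
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if complete.sum() < min_complete:
        raise ValueError(f"only {int(complete.sum())} complete cases (< {min_complete})")
    fit = logit_term(y, X, term=0)
    return _wald_result(fit, model=model, adjusted_for=tuple(covariates),
                        kind="log_odds", term=snp)


def compute_summary_associations(
    cohort: Cohort,
    instruments: Sequence[str],
    model: str = "over-dominant",
    exposure_covariates: Sequence[str] = (),
    outcome_covariates: Sequence[str] = (),
) -> SummaryAssociations:
    """One-sample summary statistics: control-only exposure stage, full-sample
    covariate-adjusted outcome stage, same genetic coding in both."""
    from .validate import exposure_association

    bx, sx, by, sy = [], [], [], []
    for snp in instruments:
        ax = exposure_association(cohort, snp, model=model, covariates=exposure_covariates)
        ay = outcome_association(cohort, snp, model=model, covariates=outcome_covariates)
        bx.append(ax.effect), sx.append(ax.se), by.append(ay.effect), sy.append(ay.se)
    return SummaryAssociations(tuple(instruments), np.array(bx), np.array(sx),
                               np.array(by), np.array(sy),
                               adjusted_for=tuple(outcome_covariates))


def ratio_estimates(summary: SummaryAssociations, second_order: bool = False):
    """Per-instrument Wald ratios theta_j = by_j / bx_j with delta-method SEs.

    First order: se_y/|bx| (default).  ``second_order`` adds the exposure-stage
    term, sqrt(se_y^2/bx^2 + by^2 se_x^2 / bx^4), for weak instruments.
    Instruments with bx = 0 are rejected.
    """
    bx, by = summary.beta_x, summary.beta_y
    if (bx == 0).any():
        bad = [s for s, b in zip(summary.snp_ids, bx) if b == 0]
        raise ValueError(f"zero exposure association for instrument(s) {bad}; ratio undefined")
    theta = by / bx
    if second_order:
        se = np.sqrt(summary.se_y**2 / bx**2 + by**2 * summary.se_x**2 / bx**4)
    else:
        se = summary.se_y / np.abs(bx)
    return theta, se


def _finish(method, theta, se, n_inst, ci=None, diagnostics=None) -> MREstimate:
    if ci is None:
        ci = (theta - Z95 * se, theta + Z95 * se)
    or_, or_ci = or_per_10pct_decrease(theta, ci=ci)
    return MREstimate(method, float(theta), float(se), (float(ci[0]), float(ci[1])),
                      or_, or_ci, n_inst, diagnostics or {})


def ivw_estimate(summary: SummaryAssociations, second_order: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance weighted mean of the ratio estimates."""
    theta_j, se_j = ratio_estimates(summary, second_order=second_order)
    w = 1.0 / se_j**2
    theta = float((w * theta_j).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    return _finish("ivw", theta, se, summary.n_instruments)


def _ml_profile(summary: SummaryAssociations, theta: float):
    """Profile log-likelihood in theta: xi_j maximized out in closed form."""
    sx2, sy2 = summary.se_x**2, summary.se_y**2
    xi = (summary.beta_x / sx2 + theta * summary.beta_y / sy2) / (1.0 / sx2 + theta**2 / sy2)
    ll = -0.5 * (((summary.beta_x - xi) ** 2) / sx2 + ((summary.beta_y - theta * xi) ** 2) / sy2)
    return float(ll.sum()), xi


def ml_estimate(summary: SummaryAssociations) -> MREstimate:
    """Maximum likelihood under bx_j ~ N(xi_j, se_x^2), by_j ~ N(theta xi_j, se_y^2).

    The nuisance means xi_j are profiled out in closed form; theta is then
    maximized numerically starting from the IVW estimate, and the SE comes from
    the observed information of the full (xi, theta) parameterization.
    Non-convergence is reported via the ``converged`` diagnostic, never
    silently replaced by IVW.
    """
    theta0 = ivw_estimate(summary).theta
    obj = lambda t: -_ml_profile(summary, t)[0]
    try:
        res = optimize.minimize_scalar(
            obj, bracket=(theta0 - 1.0, theta0 + 1.0), method="brent",
            options={"xtol": 1e-10, "maxiter": 500},
        )
    except ValueError:  # downhill bracket search failed; fall back to a bounded scan
        span = 10.0 * (1.0 + abs(theta0))
        res = optimize.minimize_scalar(
            obj, bounds=(theta0 - span, theta0 + span), method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
    theta = float(res.x)
    converged = bool(res.success) and math.isfinite(theta)
    if obj(theta) > obj(theta0):  # never report a point worse than the IVW start
        theta, converged = theta0, False
    _, xi = _ml_profile(summary, theta)
    sx2, sy2 = summary.se_x**2, summary.se_y**2
    # observed information blocks: I_xixi diagonal, I_xitheta, I_thetatheta
    a = 1.0 / sx2 + theta**2 / sy2
    b = (2 * theta * xi - summary.beta_y) / sy2
    c = (xi**2 / sy2).sum()
    info_theta = c - (b**2 / a).sum()
    if info_theta <= 0:
        converged = False
        se = float("nan")
    else:
        se = float(info_theta**-0.5)
    ll_opt, _ = _ml_profile(summary, theta)
    if not math.isfinite(se):
        raise RuntimeError("ML estimation failed: non-positive observed information")
    return _finish("ml", theta, se, summary.n_instruments,
                   diagnostics={"converged": converged, "loglik": ll_opt,
                                "n_feval": int(res.nfev)})


def _mbe_bandwidth(theta_j: np.ndarray, factor: float) -> float:
    """Modified Silverman bandwidth on the ratio estimates: MAD-based scale
    guarded by the SD, 0.9 * min(sd, 1.4826 mad) * J^(-1/5), times ``factor``."""
    sd = float(np.std(theta_j, ddof=1)) if len(theta_j) > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(theta_j - np.median(theta_j))))
    scale = min(s for s in (sd, mad) if s > 0) if (sd > 0 or mad > 0) else 0.0
    return factor * 0.9 * scale * len(theta_j) ** (-0.2)


def _kde_mode(theta_j, weights, h, fine_step=1e-4) -> float:
    """Argmax of the weighted normal-kernel density: coarse grid, then a fine
    grid at ``fine_step`` resolution around the coarse maximum."""
    lo, hi = theta_j.min() - 3 * h, theta_j.max() + 3 * h
    if hi - lo <= fine_step:
        return float(theta_j[np.argmax(weights)])
    coarse = np.linspace(lo, hi, 2001)
    dens = _weighted_density(coarse, theta_j, weights, h)
    i = int(np.argmax(dens))
    step = coarse[1] - coarse[0]
    a, b = coarse[max(i - 2, 0)], coarse[min(i + 2, len(coarse) - 1)]
    fine = np.arange(a, b + fine_step, fine_step)
    dens = _weighted_density(fine, theta_j, weights, h)
    return float(fine[np.argmax(dens)])


def _weighted_density(grid, theta_j, weights, h):
    z = (grid[:, None] - theta_j[None, :]) / h
    return (weights[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)


def mbe_estimate(
    summary: SummaryAssociations,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> MREstimate:
    """Mode-based estimate: mode of the kernel-smoothed ratio-estimate density.

    Weights are inverse-variance (set ``weighted=False`` for the unweighted
    mode).  The CI is a seeded parametric bootstrap: resample
    theta_j* ~ N(theta_j, se_j), re-estimate the mode (bandwidth recomputed per
    replicate), take the percentile interval.  With fewer than three
    instruments the mode is statistically degenerate; it is still computed and
    flagged in the diagnostics.
    """
    theta_j, se_j = ratio_estimates(summary)
    w = 1.0 / se_j**2 if weighted else np.ones_like(se_j)
    w = w / w.sum()
    diagnostics: dict = {"bootstrap_reps": n_boot, "weighted": weighted}
    if summary.n_instruments < 3:
        diagnostics["degenerate"] = "fewer than 3 instruments; mode is poorly defined"
        warnings.warn(diagnostics["degenerate"], stacklevel=2)
    h = _mbe_bandwidth(theta_j, bandwidth_factor)
    if h <= 0 or np.ptp(theta_j) == 0:
        theta = float(theta_j[0]) if np.ptp(theta_j) == 0 else float(theta_j[np.argmax(w)])
        diagnostics["zero_spread"] = True
        return _finish("mbe", theta, 0.0, summary.n_instruments, ci=(theta, theta),
                       diagnostics=diagnostics)
    theta = _kde_mode(theta_j, w, h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = rng.normal(theta_j, se_j)
        hb = _mbe_bandwidth(tb, bandwidth_factor)
        boots[b] = _kde_mode(tb, w, hb, fine_step=1e-3) if hb > 0 else tb[np.argmax(w)]
    se = float(np.std(boots, ddof=1))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    diagnostics["bandwidth"] = h
    return _finish("mbe", theta, se, summary.n_instruments, ci=ci, diagnostics=diagnostics)


def or_per_10pct_decrease(theta: float, se: Optional[float] = None, ci=None,
                          convention: str = "times_0.9"):
    """Rescale theta to the odds ratio per 10% exposure decrease.

    ``times_0.9`` (default): a 10% decrease multiplies the exposure by 0.9,
    OR = exp(theta * ln 0.9).  ``div_1.1``: interpret the decrease as division
    by 1.1, OR = exp(-theta * ln 1.1).  CI endpoints are transformed the same
    way and reordered (the transform is decreasing in theta).
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    factor = LN_09 if convention == "times_0.9" else -math.log(1.1)
    if convention not in ("times_0.9", "div_1.1"):
        raise ValueError(f"unknown convention {convention!r}")
    if ci is None:
        if se is None:
            raise ValueError("supply se or ci")
        ci = (theta - Z95 * se, theta + Z95 * se)
    or_ = math.exp(theta * factor)
    endpoints = sorted(math.exp(c * factor) for c in ci)
    return or_, (endpoints[0], endpoints[1])


def all_linear_estimates(summary: SummaryAssociations, n_boot: int = 1000,
                         seed: int = 0) -> list[MREstimate]:
    """IVW, ML and MBE on the same summary statistics, in reporting order."""
    return [
        ivw_estimate(summary),
        ml_estimate(summary),
        mbe_estimate(summary, n_boot=n_boot, seed=seed),
    ]


def estimates_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "theta": [e.theta for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci95[0] for e in estimates],
            "ci_high": [e.ci95[1] for e in estimates],
            "or_per_10pct_decrease": [e.or_per_10pct_decrease for e in estimates],
            "or_ci_low": [e.or_ci95[0] for e in estimates],
            "or_ci_high": [e.or_ci95[1] for e in estimates],
            "n_instruments": [e.n_instruments for e in estimates],
        }
    )


def tsls_grs_diagnostic(cohort: Cohort, grs: pd.Series,
                        covariates: Sequence[str] = ()) -> AssociationResult:
    """Two-stage cross-check on the genetic risk score.

    Stage 1: least squares of exposure on the GRS (plus covariates) in the full
    sample; stage 2: logistic outcome on the stage-1 fitted exposure.  The SE
    ignores first-stage uncertainty, so treat this as a diagnostic companion to
    the summary-statistic estimators, not a headline estimate.
    """
    g = grs.to_numpy(dtype=float)
    y = cohort.exposure.to_numpy(dtype=float)
    cov = [cohort.phenotypes[c].to_numpy(dtype=float)[:, None] for c in covariates]
    X1 = np.hstack([g[:, None]] + cov) if cov else g[:, None]
    keep = np.isfinite(y) & np.all(np.isfinite(X1), axis=1)
    import statsmodels.api as sm

    design = sm.add_constant(X1[keep])
    stage1 = sm.OLS(y[keep], design).fit()
    xhat = np.full_like(y, np.nan)
    xhat[keep] = stage1.fittedvalues
    X2 = np.hstack([xhat[:, None]] + cov) if cov else xhat[:, None]
    fit = logit_term(cohort.outcome.to_numpy(dtype=float), X2, term=0)
    return _wald_result(fit, model="grs-2sls", adjusted_for=tuple(covariates),
                        kind="log_odds", term="grs")
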