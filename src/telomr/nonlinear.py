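"""Semiparametric non-linear Mendelian randomization.

The sample is stratified on the *IV-free exposure* -- the residual of the
exposure after removing the genetic risk score's contribution -- so that
strata do not condition on a collider.  Within each stratum a localized
average causal effect (LACE) is the ratio of the GRS->outcome log-odds to the
GRS->exposure slope.  Three tests ask whether the LACE pattern departs from
the constant profile a linear causal effect implies:

* quadratic test: weighted linear trend of LACE on the stratum exposure mean;
* Cochran's Q: heterogeneity of the LACE estimates beyond chance;
* fractional polynomial test: does a degree-1 fractional polynomial causal
  curve (derivative c * x^(p-1), p in {-2,-1,-0.5,0,0.5,1,2,3}) fit the LACE
  profile better than the linear curve (p = 1)?

Causal curves are reconstructed either piecewise-linearly (integrating each
stratum's constant slope) or from the best fractional polynomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import SeparationError, SingularDesignError, logit_term, ols_term
from .cohort import Cohort
from .genetics import Z95

FRACPOLY_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class IVFreeExposure:
    """Residual exposure (exposure minus the GRS-predicted part)."""

    residuals: pd.Series
    coef: dict
    fit_on: str


def iv_free_exposure(
    cohort: Cohort,
    grs: pd.Series,
    covariates: Sequence[str] = (),
    fit_on: str = "controls",
) -> IVFreeExposure:
    """Regress exposure on the GRS (plus covariates) and return residuals.

    The fit is estimated in controls by default (consistent with estimating
    instrument-exposure effects outcome-free) and its coefficients are applied
    to every subject; residuals are mean-zero in the fitting set.
    """
    if fit_on not in ("controls", "all"):
        raise ValueError("fit_on must be 'controls' or 'all'")
    g = grs.reindex(cohort.phenotypes.index).to_numpy(dtype=float)
    y = cohort.exposure.to_numpy(dtype=float)
    cov = np.column_stack(
        [cohort.phenotypes[c].to_numpy(dtype=float) for c in covariates]
    ) if covariates else np.empty((len(y), 0))
    X = np.column_stack([g, cov])
    fit_mask = cohort.is_control().to_numpy() if fit_on == "controls" else np.ones(len(y), bool)
    keep = fit_mask & np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    gk = g[keep]
    if np.ptp(gk[np.isfinite(gk)]) == 0:
        raise SingularDesignError("GRS is constant in the fitting set")
    import statsmodels.api as sm

    design = sm.add_constant(X[keep])
    res = sm.OLS(y[keep], design).fit()
    fitted = np.column_stack([np.ones(len(y)), X]) @ res.params
    residuals = pd.Series(y - fitted, index=cohort.phenotypes.index, name="iv_free_exposure")
    coef = {"const": float(res.params[0]), "grs": float(res.params[1])}
    for i, c in enumerate(covariates):
        coef[c] = float(res.params[2 + i])
    return IVFreeExposure(residuals, coef, fit_on)


def stratify(residuals, k: int) -> np.ndarray:
    """Quantile-cut stratum labels 1..k on the IV-free exposure.

    Stratum sizes differ by at most one; ties are broken by stable input
    order.  Raises if fewer than ``k`` distinct values exist.
    """
    r = np.asarray(residuals, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 strata")
    if np.isnan(r).any():
        raise ValueError("residuals contain missing values")
    if len(np.unique(r)) < k:
        raise ValueError(f"only {len(np.unique(r))} distinct values for {k} strata")
    n = len(r)
    order = np.argsort(r, kind="stable")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.empty(n, dtype=int)
    start = 0
    for j, s in enumerate(sizes, start=1):
        labels[order[start : start + s]] = j
        start += s
    return labels


@dataclass(frozen=True)
class StratumResult:
    """Per-stratum first-stage, second-stage and LACE estimates."""

    k: int
    n: int
    x_mean: float
    x_range: tuple[float, float]
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    lace: float
    se_lace: float
    excluded: bool = False
    note: str = ""


def lace_estimates(
    cohort: Cohort,
    grs: pd.Series,
    strata: np.ndarray,
    covariates: Sequence[str] = (),
) -> list[StratumResult]:
    """LACE per stratum: beta_y (GRS->outcome logit) over beta_x (GRS->exposure OLS).

    The delta-method SE uses both stages,
    sqrt(se_y^2/bx^2 + by^2 se_x^2/bx^4).  Strata with a constant GRS or a
    single outcome class are flagged ``excluded`` (the non-linearity tests then
    drop them and reduce their df).
    """
    g = grs.reindex(cohort.phenotypes.index).to_numpy(dtype=float)
    y = cohort.outcome.to_numpy(dtype=float)
    x = cohort.exposure.to_numpy(dtype=float)
    cov = np.column_stack(
        [cohort.phenotypes[c].to_numpy(dtype=float) for c in covariates]
    ) if covariates else np.empty((len(y), 0))
    out: list[StratumResult] = []
    for k in sorted(np.unique(strata)):
        m = strata == k
        xs = x[m][np.isfinite(x[m])]
        x_mean = float(xs.mean())
        x_range = (float(xs.min()), float(xs.max()))
        X = np.column_stack([g[m], cov[m]])
        try:
            fx = ols_term(x[m], X, term=0)
            fy = logit_term(y[m], X, term=0)
        except (SingularDesignError, SeparationError, ValueError) as exc:
            out.append(StratumResult(int(k), int(m.sum()), x_mean, x_range,
                                     math.nan, math.nan, math.nan, math.nan,
                                     math.nan, math.nan, excluded=True, note=str(exc)))
            continue
        if fx.coef == 0:
            out.append(StratumResult(int(k), int(m.sum()), x_mean, x_range,
                                     fx.coef, fx.se, fy.coef, fy.se, math.nan, math.nan,
                                     excluded=True, note="zero first-stage slope"))
            continue
        lace = fy.coef / fx.coef
        se = math.sqrt(fy.se**2 / fx.coef**2 + fy.coef**2 * fx.se**2 / fx.coef**4)
        out.append(StratumResult(int(k), int(m.sum()), x_mean, x_range,
                                 fx.coef, fx.se, fy.coef, fy.se, lace, se))
    return out


def _usable(strata_results: Sequence[StratumResult]) -> list[StratumResult]:
    return [s for s in strata_results if not s.excluded and math.isfinite(s.lace)]


@dataclass(frozen=True)
class TrendTest:
    slope: float
    se: float
    p_value: float
    k_used: int


def quadratic_test(strata_results: Sequence[StratumResult]) -> TrendTest:
    """Weighted linear trend of LACE on the stratum exposure means.

    Weighted least squares with weights 1/se_lace^2; the p-value is the normal
    test on the slope.  A non-zero trend is what a quadratic causal effect
    induces (the derivative of a quadratic is linear in x).
    """
    use = _usable(strata_results)
    if len(use) < 3:
        raise ValueError("quadratic test needs at least 3 usable strata")
    x = np.array([s.x_mean for s in use])
    lace = np.array([s.lace for s in use])
    w = np.array([1.0 / s.se_lace**2 for s in use])
    xb = (w * x).sum() / w.sum()
    lb = (w * lace).sum() / w.sum()
    sxx = (w * (x - xb) ** 2).sum()
    slope = float((w * (x - xb) * (lace - lb)).sum() / sxx)
    se = float(sxx**-0.5)
    z = slope / se
    return TrendTest(slope, se, float(2 * stats.norm.sf(abs(z))), len(use))


@dataclass(frozen=True)
class CochranQTest:
    q: float
    df: int
    p_value: float


def cochran_q_test(strata_results: Sequence[StratumResult]) -> CochranQTest:
    """Heterogeneity of the LACE estimates around their weighted mean."""
    use = _usable(strata_results)
    if len(use) < 2:
        raise ValueError("Cochran's Q needs at least 2 usable strata")
    lace = np.array([s.lace for s in use])
    w = np.array([1.0 / s.se_lace**2 for s in use])
    mean = (w * lace).sum() / w.sum()
    q = float((w * (lace - mean) ** 2).sum())
    df = len(use) - 1
    return CochranQTest(q, df, float(stats.chi2.sf(q, df)))


@dataclass(frozen=True)
class FracPolyTest:
    best_power: float
    statistic: float
    p_value: float
    coef: float
    se_coef: float
    shift: float
    loglik_by_power: dict = field(default_factory=dict)


def _fracpoly_basis(x: np.ndarray, power: float) -> np.ndarray:
    # derivative basis of the degree-1 fractional polynomial x^p (p=0 -> log x)
    return x ** (power - 1.0)


def _fracpoly_fit(x, lace, w, power):
    g = _fracpoly_basis(x, power)
    denom = (w * g**2).sum()
    c = (w * g * lace).sum() / denom
    wrss = (w * (lace - c * g) ** 2).sum()
    return float(c), float(denom**-0.5), float(wrss)


def fracpoly_test(
    strata_results: Sequence[StratumResult],
    powers: Sequence[float] = FRACPOLY_POWERS,
) -> FracPolyTest:
    """Best degree-1 fractional polynomial versus the linear causal model.

    Each power p models the LACE profile as c * x^(p-1) (the derivative of
    c x^p; p = 0 gives the 1/x derivative of the logarithm).  Fits are by
    weighted Gaussian likelihood with the delta-method LACE variances; the
    statistic is twice the log-likelihood gain of the best power over p = 1,
    referred to chi-squared with 1 df.  Power-selection multiplicity is
    ignored, which makes the test mildly anti-conservative.
    """
    use = _usable(strata_results)
    if len(use) < 3:
        raise ValueError("fractional polynomial test needs at least 3 usable strata")
    x = np.array([s.x_mean for s in use])
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
        x = x + shift
    lace = np.array([s.lace for s in use])
    w = np.array([1.0 / s.se_lace**2 for s in use])
    fits = {}
    for p in powers:
        c, se_c, wrss = _fracpoly_fit(x, lace, w, p)
        fits[p] = (c, se_c, wrss)
    if 1.0 not in fits:
        _, _, wrss_lin = _fracpoly_fit(x, lace, w, 1.0)
    else:
        wrss_lin = fits[1.0][2]
    # prefer the linear power on ties so a flat profile reports p = 1
    best = min(fits, key=lambda p: (round(fits[p][2], 12), p != 1.0))
    c, se_c, wrss_best = fits[best]
    statistic = max(0.0, wrss_lin - wrss_best)
    p_value = float(stats.chi2.sf(statistic, 1)) if statistic > 0 else 1.0
    return FracPolyTest(float(best), float(statistic), p_value, c, se_c, shift,
                        loglik_by_power={p: -0.5 * f[2] for p, f in fits.items()})


@dataclass(frozen=True)
class CurveResult:
    method: str
    x: np.ndarray
    effect: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "effect": self.effect, "ci_low": self.ci_low,
                             "ci_high": self.ci_high, "method": self.method})


def _segment_breaks(use: Sequence[StratumResult]) -> np.ndarray:
    """Segment boundaries for the piecewise curve: overall exposure extremes at
    the ends, midpoints between consecutive stratum exposure means inside
    (stratum exposure ranges can overlap once strata come from residuals)."""
    means = np.array([s.x_mean for s in use])
    lo = min(s.x_range[0] for s in use)
    hi = max(s.x_range[1] for s in use)
    inner = (means[:-1] + means[1:]) / 2.0
    return np.concatenate([[lo], inner, [hi]])


def piecewise_curve(
    strata_results: Sequence[StratumResult],
    reference: float,
    points_per_segment: int = 25,
) -> CurveResult:
    """Causal curve by integrating each stratum's constant LACE slope.

    h is continuous, h(reference) = 0, and the pointwise variance accumulates
    the (independent) stratum variances scaled by the integrated width.
    """
    use = sorted(_usable(strata_results), key=lambda s: s.x_mean)
    if len(use) < 2:
        raise ValueError("piecewise curve needs at least 2 usable strata")
    breaks = _segment_breaks(use)
    if not (breaks[0] <= reference <= breaks[-1]):
        raise ValueError(f"reference {reference} outside observed exposure range "
                         f"[{breaks[0]}, {breaks[-1]}]")
    slopes = np.array([s.lace for s in use])
    ses = np.array([s.se_lace for s in use])
    xs = np.unique(np.concatenate(
        [np.linspace(breaks[i], breaks[i + 1], points_per_segment)
         for i in range(len(use))] + [np.array([reference])]
    ))
    effect = np.empty_like(xs)
    var = np.empty_like(xs)
    for i, xv in enumerate(xs):
        a, b = min(reference, xv), max(reference, xv)
        overlap = np.clip(np.minimum(b, breaks[1:]) - np.maximum(a, breaks[:-1]), 0.0, None)
        sign = 1.0 if xv >= reference else -1.0
        effect[i] = sign * (slopes * overlap).sum()
        var[i] = ((ses * overlap) ** 2).sum()
    half = Z95 * np.sqrt(var)
    return CurveResult("piecewise", xs, effect, effect - half, effect + half, reference)


def fracpoly_curve(
    strata_results: Sequence[StratumResult],
    fp: FracPolyTest,
    reference: float,
    n_points: int = 120,
) -> CurveResult:
    """Causal curve from the fitted fractional polynomial derivative.

    h(x) = c * (G_p(x) - G_p(ref)) with G_p the antiderivative of x^(p-1)
    (x^p / p, or ln x for p = 0); the CI is the delta-method band on c.
    """
    use = _usable(strata_results)
    lo = min(s.x_range[0] for s in use)
    hi = max(s.x_range[1] for s in use)
    if not (lo <= reference <= hi):
        raise ValueError(f"reference {reference} outside observed exposure range [{lo}, {hi}]")
    xs = np.linspace(lo, hi, n_points)
    G = _fracpoly_antiderivative
    gx = G(xs + fp.shift, fp.best_power) - G(reference + fp.shift, fp.best_power)
    effect = fp.coef * gx
    half = Z95 * fp.se_coef * np.abs(gx)
    return CurveResult("fracpoly", xs, effect, effect - half, effect + half, reference)


def _fracpoly_antiderivative(x: np.ndarray, power: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if power == 0.0:
        return np.log(x)
    return x**power / power


@dataclass(frozen=True)
class NonlinearReport:
    """Strata, the three non-linearity tests and the causal curves."""

    strata: list[StratumResult]
    quadratic: TrendTest
    cochran_q: CochranQTest
    fracpoly: FracPolyTest
    k: int
    curves: dict[str, CurveResult] = field(default_factory=dict)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": ["quadratic", "cochran_q", "fracpoly"],
                "statistic": [self.quadratic.slope / self.quadratic.se,
                              self.cochran_q.q, self.fracpoly.statistic],
                "df": [np.nan, self.cochran_q.df, 1],
                "p_value": [self.quadratic.p_value, self.cochran_q.p_value,
                            self.fracpoly.p_value],
                "detail": [f"slope={self.quadratic.slope:.6g}",
                           f"df={self.cochran_q.df}",
                           f"best_power={self.fracpoly.best_power:g}"],
            }
        )

    def strata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [s.k for s in self.strata],
                "n": [s.n for s in self.strata],
                "x_mean": [s.x_mean for s in self.strata],
                "x_low": [s.x_range[0] for s in self.strata],
                "x_high": [s.x_range[1] for s in self.strata],
                "beta_x": [s.beta_x for s in self.strata],
                "se_x": [s.se_x for s in self.strata],
                "beta_y": [s.beta_y for s in self.strata],
                "se_y": [s.se_y for s in self.strata],
                "lace": [s.lace for s in self.strata],
                "se_lace": [s.se_lace for s in self.strata],
                "excluded": [s.excluded for s in self.strata],
            }
        )


def nonlinear_mr(
    cohort: Cohort,
    grs: pd.Series,
    k: int = 5,
    covariates: Sequence[str] = (),
    reference: Optional[float] = None,
    with_curves: bool = True,
) -> NonlinearReport:
    """Run the full semiparametric stage: IV-free stratification, LACE, the
    three non-linearity tests and (optionally) both causal curves.

    ``reference`` defaults to the mean exposure; curves report the causal
    log-odds difference relative to that point.
    """
    if not 2 <= k <= 10:
        raise ValueError("k must be between 2 and 10")
    ivf = iv_free_exposure(cohort, grs, covariates=covariates)
    strata = stratify(ivf.residuals.to_numpy(), k)
    results = lace_estimates(cohort, grs, strata, covariates=covariates)
    quad = quadratic_test(results)
    q = cochran_q_test(results)
    fp = fracpoly_test(results)
    curves: dict[str, CurveResult] = {}
    if with_curves:
        ref = float(cohort.exposure.mean()) if reference is None else reference
        curves["piecewise"] = piecewise_curve(results, ref)
        curves["fracpoly"] = fracpoly_curve(results, fp, ref)
    return NonlinearReport(results, quad, q, fp, k, curves)
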