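"""Conventional case-control analyses alongside the MR pipeline.

Descriptive group comparisons (the classic "Table 1"), the covariate-adjusted
exposure-outcome logistic regression, and the exposure-quintile case/control
comparison that feeds a box plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import SingularDesignError, logit_term
from .cohort import Cohort
from .genetics import Z95


@dataclass(frozen=True)
class DescriptiveRow:
    variable: str
    level: Optional[str]
    summary_cases: str
    summary_controls: str
    test_used: str
    p_value: float


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics (numpy default)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(q1), float(med), float(q3)


def _is_normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(np.unique(x)) < 3 or len(x) < 3:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue >= alpha


def describe_and_test(
    cohort: Cohort,
    variable_specs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Group summaries and between-group tests, one row per variable (or level).

    Continuous variables: mean +/- SD with Welch's t test when both groups pass
    Shapiro-Wilk at alpha = 0.05, otherwise median (IQR) with the Mann-Whitney
    U test (normal approximation, tie-corrected).  Categorical variables:
    n (%) per level with a chi-squared test on the full contingency table.
    ``variable_specs`` lists (name, kind) pairs with kind "continuous" or
    "categorical"; by default every covariate plus the exposure is described
    and 0/1 variables are treated as categorical.
    """
    if variable_specs is None:
        variable_specs = []
        for name in ["exposure"] + cohort.covariate_names:
            vals = cohort.phenotypes[name].dropna().unique()
            kind = "categorical" if set(vals) <= {0, 1} or len(vals) <= 3 else "continuous"
            variable_specs.append((name, kind))
    case_mask = cohort.phenotypes["outcome"] == 1
    rows: list[DescriptiveRow] = []
    for name, kind in variable_specs:
        series = cohort.phenotypes[name]
        xc = series[case_mask].dropna().to_numpy(dtype=float)
        xn = series[~case_mask].dropna().to_numpy(dtype=float)
        if xc.size == 0 and xn.size == 0:
            warnings.warn(f"variable {name!r} is entirely missing; skipped", stacklevel=2)
            continue
        if kind == "continuous":
            rows.append(_continuous_row(name, xc, xn))
        else:
            rows.extend(_categorical_rows(name, xc, xn))
    return pd.DataFrame([r.__dict__ for r in rows])


def _continuous_row(name: str, xc: np.ndarray, xn: np.ndarray) -> DescriptiveRow:
    normal = _is_normalish(xc) and _is_normalish(xn)
    if normal:
        summ = lambda x: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
        if np.ptp(xc) == 0 and np.ptp(xn) == 0 and xc.mean() == xn.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(xc, xn, equal_var=False).pvalue)
        test = "t"
    else:
        def summ(x):
            q1, med, q3 = _quartiles(x)
            return f"{med:.2f} ({q1:.2f}, {q3:.2f})"
        if np.array_equal(np.sort(xc), np.sort(xn)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xc, xn, method="asymptotic").pvalue)
        test = "mann-whitney"
    return DescriptiveRow(name, None, summ(xc), summ(xn), test, p)


def _categorical_rows(name: str, xc: np.ndarray, xn: np.ndarray) -> list[DescriptiveRow]:
    levels = sorted(set(xc) | set(xn))
    table = np.array(
        [[(xc == lv).sum() for lv in levels], [(xn == lv).sum() for lv in levels]]
    ).T
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    rows = []
    for lv in levels:
        nc, nn = int((xc == lv).sum()), int((xn == lv).sum())
        rows.append(
            DescriptiveRow(
                name,
                f"{lv:g}",
                f"{nc} ({100 * nc / max(len(xc), 1):.1f}%)",
                f"{nn} ({100 * nn / max(len(xn), 1):.1f}%)",
                "chi-squared",
                p,
            )
        )
    return rows


@dataclass(frozen=True)
class ExposureORResult:
    odds_ratio: float
    ci95: tuple[float, float]
    log_or: float
    se: float
    p_value: float
    n_used: int
    adjusted_for: tuple[str, ...]


def adjusted_exposure_regression(
    cohort: Cohort, covariates: Sequence[str] = (), min_complete: int = 20
) -> ExposureORResult:
    """Observational OR of the outcome per unit ln-exposure, covariate adjusted.

    Logistic regression of case status on ln-exposure plus covariates.  A rank
    deficient design (e.g. the exposure duplicated as a covariate) raises
    :class:`SingularDesignError`.
    """
    y = cohort.outcome.to_numpy(dtype=float)
    X = np.column_stack(
        [cohort.exposure.to_numpy(dtype=float)]
        + [cohort.phenotypes[c].to_numpy(dtype=float) for c in covariates]
    )
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if complete.sum() < min_complete:
        raise ValueError(f"only {int(complete.sum())} complete cases (< {min_complete})")
    fit = logit_term(y, X, term=0)
    half = Z95 * fit.se
    return ExposureORResult(
        odds_ratio=float(np.exp(fit.coef)),
        ci95=(float(np.exp(fit.coef - half)), float(np.exp(fit.coef + half))),
        log_or=fit.coef,
        se=fit.se,
        p_value=fit.p_value,
        n_used=fit.n_used,
        adjusted_for=tuple(covariates),
    )


def quintile_comparison(cohort: Cohort, k: int = 5) -> pd.DataFrame:
    """Case/control exposure summaries within pooled exposure quintiles.

    Quantile cut points pool cases and controls.  Within each group the
    summaries are plot-ready box-plot statistics (median, quartiles, whiskers
    at 1.5 IQR clipped to the data); the per-quintile p compares case versus
    control exposure by Mann-Whitney.
    """
    if cohort.n < 50:
        raise ValueError("quintile comparison needs at least 50 subjects")
    expo = cohort.exposure
    quint = pd.qcut(expo.rank(method="first"), k, labels=range(1, k + 1))
    rows = []
    for q in range(1, k + 1):
        mask = (quint == q).to_numpy()
        sub = cohort.phenotypes.loc[mask]
        xc = sub.loc[sub["outcome"] == 1, "exposure"].dropna().to_numpy()
        xn = sub.loc[sub["outcome"] == 0, "exposure"].dropna().to_numpy()
        if xc.size == 0 or xn.size == 0:
            p = np.nan
            note = "empty group"
        else:
            p = float(stats.mannwhitneyu(xc, xn, method="asymptotic").pvalue)
            note = ""
        for label, x in (("cases", xc), ("controls", xn)):
            if x.size:
                q1, med, q3 = _quartiles(x)
                iqr = q3 - q1
                lo = float(x[x >= q1 - 1.5 * iqr].min())
                hi = float(x[x <= q3 + 1.5 * iqr].max())
            else:
                q1 = med = q3 = lo = hi = np.nan
            rows.append(
                {"quintile": q, "group": label, "n": int(x.size), "median": med,
                 "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi,
                 "p_value": p, "note": note}
            )
    return pd.DataFrame(rows)
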