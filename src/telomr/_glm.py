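"""Thin wrappers around statsmodels OLS / logistic fits.

All regression stages (instrument-exposure, pleiotropy screen, genotype-outcome,
LACE stages, observational models) funnel through these two helpers so that
missing-data handling, separation detection and the returned (coef, se, p)
contract stay in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (e.g. constant genotype code)."""


class SeparationError(RuntimeError):
    """Quasi-complete separation or non-convergence in a logistic fit."""


@dataclass(frozen=True)
class FitTerm:
    coef: float
    se: float
    p_value: float
    n_used: int


def _prepare(y, X) -> tuple[np.ndarray, np.ndarray, int]:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"design matrix rank {rank} < {design.shape[1]} columns (constant or collinear term)"
        )
    return y, design, int(len(y))


def ols_term(y, X, term: int = 0) -> FitTerm:
    """Least-squares fit of y on [1, X]; coefficient ``term`` of X (0-based).

    A constant response is a valid degenerate input (e.g. exposure replaced by
    a constant): the slope is exactly 0 with p = 1.
    """
    y, design, n = _prepare(y, X)
    if n < design.shape[1]:
        raise ValueError(f"too few complete cases ({n}) for {design.shape[1]} parameters")
    if np.ptp(y) == 0.0:
        return FitTerm(0.0, 0.0, 1.0, n)
    res = sm.OLS(y, design).fit()
    j = term + 1
    return FitTerm(float(res.params[j]), float(res.bse[j]), float(res.pvalues[j]), n)


def logit_term(y, X, term: int = 0, max_abs_coef: float = 15.0) -> FitTerm:
    """Logistic fit of a binary y on [1, X]; coefficient ``term`` of X.

    Raises :class:`SeparationError` on quasi-complete separation or
    non-convergence rather than returning a divergent estimate.
    """
    y, design, n = _prepare(y, X)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is single-class in this subset")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if np.max(np.abs(res.params)) > max_abs_coef:
        raise SeparationError("divergent logistic coefficients suggest quasi-separation")
    j = term + 1
    return FitTerm(float(res.params[j]), float(res.bse[j]), float(res.pvalues[j]), n)
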