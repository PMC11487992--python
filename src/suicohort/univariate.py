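"""Univariate logistic regression with Wald inference and a closed-form
contingency oracle.

One categorical predictor per model, fitted by Newton-Raphson maximum
likelihood.  For a single categorical predictor the maximum-likelihood
odds ratios equal the contingency-table cross-product ratios, so
:func:`contingency_or_oracle` provides an independent closed-form check
of the iterative fitter.  Significance flags use the study's Bonferroni
convention: alpha = 0.05 divided by the variable's total level count
(0.025 for two-level, 0.017 for three-level variables).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .coding import CodingError
from .descriptives import ContingencyTable, crosstab, format_percent

logger = logging.getLogger(__name__)

__all__ = [
    "Z_95",
    "FittedModel",
    "PerfectSeparationError",
    "ZeroCellError",
    "fit_logistic",
    "log_likelihood",
    "contingency_or_oracle",
    "UnivariateLogit",
    "UnivariateResults",
    "univariate_table",
]

#: Two-sided 95% normal quantile used throughout for Wald intervals.
Z_95 = 1.959964

_SEPARATION_BOUND = 40.0  # |log-odds| beyond any plausible MLE on real cells


def wald_ci(estimate: float, se: float) -> tuple[float, float]:
    """Odds-scale 95% Wald interval; saturates to inf rather than warn
    when a ridge-stabilised fit leaves a huge standard error."""
    with np.errstate(over="ignore"):
        return float(np.exp(estimate - Z_95 * se)), float(np.exp(estimate + Z_95 * se))


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded (separated data) and no ridge was allowed."""


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; the closed-form odds ratio is undefined.

    Callers should fall back to :func:`fit_logistic` with a ridge.
    """


@dataclass
class FittedModel:
    """Maximum-likelihood logistic fit."""

    terms: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    n_obs: int
    n_iter: int
    ridge_used: float = 0.0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict_eta(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params


def log_likelihood(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at ``params`` (numerically stable)."""
    eta = X @ params
    # log sigma(s*eta) with s = +/-1 via logaddexp
    s = 2.0 * y - 1.0
    return float(-np.logaddexp(0.0, -s * eta).sum())


def _newton(X, y, ridge, tol, max_iter, start):
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    pen = ridge * np.eye(p)
    llf = log_likelihood(beta, X, y) - 0.5 * ridge * beta @ beta
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu) - ridge * beta
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + pen
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving guard: Newton on the logistic likelihood is
        # usually monotone, but saturated cells can overshoot
        for _ in range(30):
            cand = beta + step
            cand_llf = log_likelihood(cand, X, y) - 0.5 * ridge * cand @ cand
            if cand_llf >= llf - 1e-12:
                break
            step = step / 2.0
        beta, llf = cand, cand_llf
        if np.max(np.abs(beta)) > _SEPARATION_BOUND and ridge == 0.0:
            separated = True
            break
        if np.max(np.abs(score)) < tol or np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X + pen
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, converged, separated, it


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    terms: tuple[str, ...] | None = None,
    ridge: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Newton-Raphson maximum-likelihood logistic regression.

    Convergence when the largest absolute score component or parameter
    change falls below ``tol`` (default 1e-10), capped at ``max_iter``
    iterations.  ``ridge`` is a fallback L2 penalty engaged only when
    separation is detected (parameters diverging past any plausible
    finite MLE); with ``ridge=0`` separated data raises
    :class:`PerfectSeparationError`.  Non-convergence is flagged on the
    returned model, never silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    terms = terms or tuple(f"x{j}" for j in range(X.shape[1]))

    beta, cov, converged, separated, it = _newton(X, y, 0.0, tol, max_iter, start)
    ridge_used = 0.0
    if separated:
        if ridge <= 0.0:
            raise PerfectSeparationError(
                "perfect separation detected; refit with a small ridge"
            )
        beta, cov, converged, separated, it = _newton(
            X, y, ridge, tol, max_iter, start
        )
        ridge_used = ridge
    if not converged:
        logger.warning(
            "logistic fit did not converge in %d iterations (max |param| %.3g)",
            it,
            float(np.max(np.abs(beta))),
        )
    return FittedModel(
        terms=tuple(terms),
        params=beta,
        cov=cov,
        llf=log_likelihood(beta, X, y),
        converged=converged,
        n_obs=len(y),
        n_iter=it,
        ridge_used=ridge_used,
    )


def contingency_or_oracle(table: ContingencyTable) -> pd.DataFrame:
    """Closed-form odds ratios and Wald 95% CIs from a contingency table.

    For each non-reference level with cells a = events, b = non-events
    and reference cells c, d: OR = (a*d)/(b*c) and
    CI = exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    c = int(table.events[0])
    d = int(table.totals[0] - table.events[0])
    rows = []
    for level, n, e in zip(table.levels[1:], table.totals[1:], table.events[1:]):
        a = int(e)
        b = int(n - e)
        if min(a, b, c, d) <= 0:
            raise ZeroCellError(
                f"zero cell for level {level!r}; use fit_logistic with a ridge"
            )
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        rows.append(
            {
                "level": level,
                "odds_ratio": np.exp(log_or),
                "ci_low": np.exp(log_or - Z_95 * se),
                "ci_high": np.exp(log_or + Z_95 * se),
                "log_or": log_or,
                "se": se,
            }
        )
    return pd.DataFrame(rows)


class UnivariateLogit:
    """Logistic model of one binary outcome on one categorical predictor.

    Parameters
    ----------
    data : DataFrame of coded records (complete cases are taken per
        (variable, outcome) pair, matching the study's per-variable Ns).
    variable : coded column name.
    outcome : "si" or "sa" (any boolean column).
    levels : ordered level labels, reference first.
    """

    def __init__(self, data: pd.DataFrame, variable: str, outcome: str,
                 levels: tuple[str, ...]):
        self.variable = variable
        self.outcome = outcome
        self.levels = tuple(levels)
        self.data = data[data[variable].notna() & data[outcome].notna()]
        seen = set(self.data[variable].unique())
        undeclared = seen - set(self.levels)
        if undeclared:
            raise CodingError(f"undeclared level(s) {sorted(undeclared)}")

    def design(self) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
        x = self.data[self.variable]
        cols = [np.ones(len(x))]
        terms = ["intercept"]
        for level in self.levels[1:]:
            if (x == level).sum() == 0:
                continue  # empty level dropped to keep full column rank
            cols.append((x == level).to_numpy(dtype=float))
            terms.append(level)
        X = np.column_stack(cols)
        y = self.data[self.outcome].to_numpy(dtype=float)
        return X, y, tuple(terms)

    def fit(self, ridge: float = 1e-8) -> "UnivariateResults":
        X, y, terms = self.design()
        model = fit_logistic(X, y, terms=terms, ridge=ridge)
        table = crosstab(self.data, self.variable, self.outcome, self.levels)
        return UnivariateResults(self, model, table)


class UnivariateResults:
    """Per-level odds ratios, Wald CIs and Bonferroni significance."""

    def __init__(self, model: UnivariateLogit, fitted: FittedModel,
                 table: ContingencyTable):
        self.model = model
        self.fitted = fitted
        self.table = table
        # the printed Bonferroni rule divides by the total level count
        self.adjusted_alpha = round(0.05 / len(model.levels), 3)

    def summary(self) -> pd.DataFrame:
        """Tidy per-level table: counts, percentage, OR (95% CI), Wald
        p-value and the Bonferroni significance star.  The reference
        level is reported with OR exactly 1 and no interval."""
        m = self.fitted
        se = m.bse
        by_term = {t: i for i, t in enumerate(m.terms)}
        rows = []
        for level, n, e in zip(self.table.levels, self.table.totals, self.table.events):
            row = {
                "variable": self.model.variable,
                "level": level,
                "n": int(n),
                "events": int(e),
                "pct": format_percent(e / n, 2) if n else "",
                "reference": level == self.table.reference,
            }
            if level == self.table.reference:
                row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan,
                           p_value=np.nan, significant=False)
            elif level in by_term:
                j = by_term[level]
                b, s = m.params[j], se[j]
                z = b / s
                p = 2 * norm.sf(abs(z))
                lo, hi = wald_ci(b, s)
                row.update(
                    odds_ratio=float(np.exp(b)),
                    ci_low=lo,
                    ci_high=hi,
                    p_value=float(p),
                    significant=bool(p < self.adjusted_alpha),
                )
            else:  # level empty in the data
                row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p_value=np.nan, significant=False)
            rows.append(row)
        return pd.DataFrame(rows)


def univariate_table(
    records: pd.DataFrame, variable: str, outcome: str, levels: tuple[str, ...]
) -> UnivariateResults:
    """Fit and summarise one univariate model (convenience wrapper)."""
    return UnivariateLogit(records, variable, outcome, levels).fit()
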