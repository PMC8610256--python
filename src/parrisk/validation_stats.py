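"""Model fitting and performance statistics for binary risk prediction.

Implements maximum-likelihood logistic regression via iteratively reweighted
least squares (IRLS), the concordance (C) statistic with a DeLong confidence
interval, the Brier score, the le Cessie-van Houwelingen-Copas-Hosmer
unweighted sum-of-squares global goodness-of-fit test, and the per-score
calibration table.

The unweighted sum-of-squares test standardises T = sum_i (y_i - p_i)^2 by
its estimated null moments: E[T] = sum_i p_i (1 - p_i) and, writing
d_i = 1 - 2 p_i and V = diag(p_i (1 - p_i)),

    Var[T - E[T]] = d' (V - V X (X' V X)^{-1} X' V) d,

the correction term accounting for the estimated coefficients.  The
standardised statistic is compared with a standard normal, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "wald_ci",
    "profile_likelihood_ci",
    "c_statistic",
    "brier_score",
    "gof_unweighted_ss",
    "calibration_table",
]

IRLS_TOL = 1e-8
IRLS_MAXITER = 100


class SeparationError(RuntimeError):
    """The likelihood has no finite maximiser (perfect separation)."""


@dataclass
class LogisticFit:
    """Converged (or diagnosed) maximum-likelihood logistic regression.

    ``params`` holds the intercept first, then one slope per design column;
    ``cov`` is the inverse observed information; ``fitted`` are the in-sample
    probabilities.
    """

    params: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    design: np.ndarray          # includes the intercept column
    y: np.ndarray
    columns: tuple[str, ...]    # names of the design columns incl. intercept
    diagnostic: str = ""

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        design = np.column_stack([np.ones(len(X)), X])
        return expit(design @ self.params)


def _as_design(X, add_intercept: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(map(str, X.columns))
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = tuple(f"x{i}" for i in range(arr.shape[1]))
    if add_intercept:
        arr = np.column_stack([np.ones(len(arr)), arr])
        names = ("intercept", *names)
    return arr, names


def _check_rank(design: np.ndarray, names: tuple[str, ...]) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, piv = qr(design, mode="economic", pivoting=True)
        collinear = sorted(names[i] for i in piv[rank:])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} of "
            f"{design.shape[1]}); collinear columns: {collinear}"
        )


def fit_logistic(
    X,
    y,
    *,
    add_intercept: bool = True,
    offset: np.ndarray | None = None,
    tol: float = IRLS_TOL,
    maxiter: int = IRLS_MAXITER,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence is declared when the largest absolute coefficient change
    drops below ``tol`` (default 1e-8) within ``maxiter`` (default 100)
    iterations.  The covariance is the inverse observed information at the
    optimum.  Diverging coefficients (perfect separation) are reported as a
    non-converged fit with a diagnostic rather than silently returned.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    design, names = _as_design(X, add_intercept)
    n, k = design.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")
    _check_rank(design, names)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(k)
    converged = False
    diagnostic = ""
    it = 0
    for it in range(1, maxiter + 1):
        eta = design @ beta + off
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        # working response for the weighted least-squares step
        z = (eta - off) + (y - p) / w
        wx = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            diagnostic = f"singular weighted information at iteration {it}: {exc}"
            break
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    eta = design @ beta + off
    p = np.clip(expit(eta), 1e-15, 1.0 - 1e-15)
    loglik = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    if not converged and not diagnostic:
        diagnostic = (
            f"IRLS did not converge in {maxiter} iterations "
            f"(max |coef| = {np.max(np.abs(beta)):.3g}); possible perfect "
            "separation"
        )
    w = p * (1.0 - p)
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return LogisticFit(
        params=beta, cov=cov, fitted=p, loglik=loglik, converged=converged,
        n_iter=it, design=design, y=y, columns=names, diagnostic=diagnostic,
    )


def wald_ci(fit: LogisticFit, level: float = 0.95) -> np.ndarray:
    """Per-coefficient Wald interval on the log-odds scale, shape (k, 2)."""
    zcrit = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.diag(fit.cov))
    return np.column_stack([fit.params - zcrit * se, fit.params + zcrit * se])


def profile_likelihood_ci(
    fit: LogisticFit, index: int, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood interval for one coefficient.

    Finds the values of the coefficient at which twice the log-likelihood
    drop from the maximum equals the chi-square(1) quantile, refitting the
    remaining coefficients with the profiled term as a fixed offset.
    """
    from scipy.optimize import brentq

    cutoff = chi2.ppf(level, df=1)
    keep = [i for i in range(fit.design.shape[1]) if i != index]
    xj = fit.design[:, index]
    sub = fit.design[:, keep]

    def deviance_gap(bj: float) -> float:
        prof = fit_logistic(
            sub, fit.y, add_intercept=False, offset=bj * xj
        )
        return 2.0 * (fit.loglik - prof.loglik) - cutoff

    mle = fit.params[index]
    se = max(float(np.sqrt(fit.cov[index, index])), 1e-3)
    lo_bracket, hi_bracket = mle, mle
    for _ in range(60):
        lo_bracket -= se
        if deviance_gap(lo_bracket) > 0:
            break
    for _ in range(60):
        hi_bracket += se
        if deviance_gap(hi_bracket) > 0:
            break
    lo = brentq(deviance_gap, lo_bracket, mle, xtol=1e-8)
    hi = brentq(deviance_gap, mle, hi_bracket, xtol=1e-8)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Discrimination and accuracy
# ---------------------------------------------------------------------------


def c_statistic(values, y, level: float = 0.95) -> tuple[float, float, float]:
    """Concordance statistic with a DeLong confidence interval.

    C is the probability that a random case outranks a random non-case, ties
    counted one half; computed via midranks, which equals the all-pairs
    definition exactly.  The variance follows DeLong's case/control placement
    decomposition.
    """
    values = np.asarray(values, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    cases = values[y == 1]
    controls = values[y == 0]
    m, n0 = len(cases), len(controls)
    if m == 0 or n0 == 0:
        raise ValueError("C statistic undefined: both outcome classes required")

    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    ctrl_ranks = rankdata(controls)
    # placement values: fraction of the other class each subject outranks
    v10 = (all_ranks[:m] - case_ranks) / n0
    v01 = 1.0 - (all_ranks[m:] - ctrl_ranks) / m
    auc = float(np.mean(v10))

    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n0))
    zcrit = norm.ppf(0.5 + level / 2.0)
    return auc, max(0.0, auc - zcrit * se), min(1.0, auc + zcrit * se)


def brier_score(p_hat, y) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p_hat = np.asarray(p_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    return float(np.mean((y - p_hat) ** 2))


def gof_unweighted_ss(fit: LogisticFit) -> tuple[float, float, float]:
    """Unweighted sum-of-squares global goodness-of-fit test.

    Returns ``(T, z, p)`` where T is the residual sum of squares, z its
    standardisation by the estimated null mean and variance (correcting for
    estimated coefficients), and p the two-sided normal p-value.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    p = fit.fitted
    y = fit.y
    X = fit.design
    T = float(np.sum((y - p) ** 2))
    expectation = float(np.sum(p * (1.0 - p)))
    d = 1.0 - 2.0 * p
    v = p * (1.0 - p)
    xv = X.T @ (X * v[:, None])          # X' V X
    xvd = X.T @ (v * d)                  # X' V d
    try:
        correction = float(xvd @ np.linalg.solve(xv, xvd))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular X'VX in goodness-of-fit variance: {exc}")
    variance = float(d @ (v * d)) - correction
    if variance <= 1e-10 * max(1.0, expectation):
        # saturated limit: the residual direction is entirely projected out
        # and T equals its expectation — perfect calibration, nothing to test
        if abs(T - expectation) <= 1e-6 * max(1.0, expectation):
            return T, 0.0, 1.0
        raise ValueError("non-positive variance estimate in goodness of fit")
    z = (T - expectation) / np.sqrt(variance)
    return T, float(z), float(2.0 * norm.sf(abs(z)))


def calibration_table(fit: LogisticFit, scores, y) -> pd.DataFrame:
    """Observed vs model-predicted risk per distinct raw score value.

    One row per score value, sorted ascending, with the number of patients at
    that value as plotting weight; weights sum to the cohort size.
    """
    scores = np.asarray(scores)
    y = np.asarray(y, dtype=float).ravel()
    rows = []
    for s in np.unique(scores):
        mask = scores == s
        rows.append(
            {
                "score": int(s),
                "n": int(mask.sum()),
                "observed": float(y[mask].mean()),
                "predicted": float(expit(fit.intercept + fit.params[1] * s)),
            }
        )
    return pd.DataFrame(rows)
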