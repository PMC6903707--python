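"""Low-level regression primitives shared across modules.

Plain OLS with analytic standard errors and a maximum-likelihood logistic
fit by iteratively reweighted least squares (IRLS) with step-halving and a
perfect-separation monitor. The logistic routine accepts fractional
responses in [0, 1], which the simulator uses to compute deterministic
expected-outcome (probability-limit) fits.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit


def _as_covariate_matrix(covariates, n: int) -> Tuple[np.ndarray, List[str]]:
    """Coerce covariates to a float design block (without intercept/dosage)."""
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        mat = covariates.to_numpy(dtype=float)
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"covar_{j}" for j in range(mat.shape[1])]
    if mat.shape[0] != n:
        raise ValueError("covariate matrix row count must match phenotype length")
    return mat, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the first column that is collinear with its predecessors."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
            raise ValueError(f"design matrix is rank-deficient: column '{names[j]}' is collinear")
    raise ValueError("design matrix is rank-deficient")


def _ols_fit(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients and standard errors; returns (beta, se, dof)."""
    n, k = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        return beta, np.full(k, np.nan), dof
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    return beta, se, dof


def _logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_beta: float = 20.0,
    beta0: np.ndarray = None,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit by IRLS (Newton with step-halving).

    Convergence: max |score| < tol. Perfect separation is monitored via a
    diverging coefficient (|beta_j| > separation_beta) and reported as a
    failure flag rather than an exception. ``beta0`` warm-starts the iteration
    (per-variant genome scans reuse the covariate-only fit). Returns
    (beta, se, converged).
    """
    n, k = X.shape
    ybar = float(np.mean(y))
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("logistic regression requires both classes present")
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.zeros(k)
        beta[0] = np.log(ybar / (1.0 - ybar))  # intercept warm start
    p = expit(X @ beta)
    score = X.T @ (y - p)
    snorm = float(np.max(np.abs(score)))
    converged = snorm < tol
    for _ in range(max_iter):
        if converged:
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        # halve the step until the score norm stops growing (stabilizes
        # poorly conditioned strata; full Newton steps accept immediately)
        scale = 1.0
        for _ in range(8):
            cand = beta + scale * step
            pc = expit(X @ cand)
            sc = X.T @ (y - pc)
            scn = float(np.max(np.abs(sc)))
            if scn < snorm or scn < tol:
                break
            scale *= 0.5
        beta, p, score, snorm = cand, pc, sc, scn
        converged = snorm < tol
        if np.max(np.abs(beta)) > separation_beta:
            return beta, np.full(k, np.nan), False
    if not converged:
        return beta, np.full(k, np.nan), False
    w = np.clip(p * (1.0 - p), 1e-10, None)
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return beta, np.full(k, np.nan), False
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, True


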