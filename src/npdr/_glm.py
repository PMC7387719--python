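"""In-package GLM fitting kernels for projected-distance regression.

Two routes to the same maximum-likelihood estimates:

* :func:`irls_logistic` — dense Newton/IRLS for an arbitrary design matrix
  (used when covariate diff columns are present);
* :func:`grouped_logistic` — batched IRLS on grouped sufficient statistics.
  A dosage-derived diff predictor takes at most three distinct values, so
  the single-predictor logistic likelihood depends on the data only through
  per-level (total, success) counts; fitting on those counts is exact and
  lets thousands of SNPs be fitted simultaneously with array arithmetic.

Both report Wald standard errors from the observed information at the MLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["irls_logistic", "grouped_logistic", "grouped_linear", "GlmFit"]

#: |beta| beyond which a non-converged logistic fit is called separated.
_SEPARATION_BETA = 30.0


@dataclass
class GlmFit:
    beta: np.ndarray
    cov: np.ndarray | None
    converged: bool
    separated: bool = False


def irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                  tol: float = 1e-10, start: np.ndarray | None = None) -> GlmFit:
    """Newton-Raphson logistic MLE with step halving.

    ``X`` includes the intercept column; ``y`` is 0/1.  ``start`` warm-starts
    the iteration (e.g. from a shared covariates-only fit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    beta = np.zeros(d) if start is None else np.asarray(start, dtype=float).copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        # log-likelihood via logaddexp for stability
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        # halve until likelihood does not decrease
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(score)) < tol and ll - ll_old < 1e-12:
            converged = True
            break
        if np.max(np.abs(step)) < 1e-12:
            converged = np.max(np.abs(score)) < 1e-6
            break
        ll_old = ll
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-300, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    separated = (not converged) or bool(np.max(np.abs(beta)) > _SEPARATION_BETA)
    return GlmFit(beta=beta, cov=cov, converged=converged, separated=separated)


def grouped_logistic(levels: np.ndarray, n_total: np.ndarray, n_success: np.ndarray,
                     max_iter: int = 60, tol: float = 1e-10):
    """Batched intercept+slope logistic MLE from per-level counts.

    Parameters
    ----------
    levels : (L,) predictor values (e.g. AM diff levels 0, 0.5, 1).
    n_total, n_success : (S, L) counts of pairs and of "success" (miss)
        pairs at each level, one row per SNP.

    Returns
    -------
    dict of (S,) arrays: ``beta0``, ``beta1``, ``se1``, ``converged``,
    ``degenerate`` (predictor constant among observed pairs), ``separated``.
    """
    x = np.asarray(levels, dtype=float)
    N = np.asarray(n_total, dtype=float)
    Y = np.asarray(n_success, dtype=float)
    S, L = N.shape

    present = N > 0
    n_levels = present.sum(axis=1)
    degenerate = n_levels < 2
    # response constant across all pairs -> no information about the slope
    tot = N.sum(axis=1)
    succ = Y.sum(axis=1)
    degenerate |= (succ == 0) | (succ == tot)

    b0 = np.zeros(S)
    b1 = np.zeros(S)
    active = ~degenerate
    # warm start for the intercept at the empirical logit
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.clip(succ / np.maximum(tot, 1), 1e-6, 1 - 1e-6)
    b0[active] = np.log(p0[active] / (1 - p0[active]))

    converged = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active & ~converged)
        if idx.size == 0:
            break
        eta = b0[idx, None] + b1[idx, None] * x[None, :]
        mu = expit(eta)
        W = N[idx] * mu * (1 - mu)
        R = Y[idx] - N[idx] * mu
        s0 = R.sum(axis=1)
        s1 = (R * x).sum(axis=1)
        h00 = W.sum(axis=1)
        h01 = (W * x).sum(axis=1)
        h11 = (W * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01
        ok = det > 1e-300
        step0 = np.where(ok, (h11 * s0 - h01 * s1) / np.where(ok, det, 1.0), 0.0)
        step1 = np.where(ok, (h00 * s1 - h01 * s0) / np.where(ok, det, 1.0), 0.0)
        # crude trust region against overshoot on near-separated tables
        scale = np.maximum(1.0, np.maximum(np.abs(step0), np.abs(step1)) / 5.0)
        b0[idx] += step0 / scale
        b1[idx] += step1 / scale
        done = (np.maximum(np.abs(s0), np.abs(s1)) < tol) | ~ok
        converged[idx[done]] = True

    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = expit(eta)
    W = N * mu * (1 - mu)
    h00 = W.sum(axis=1)
    h01 = (W * x).sum(axis=1)
    h11 = (W * x * x).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / np.where(det > 0, det, 1.0), np.nan))
    separated = ~degenerate & (~converged | (np.abs(b1) > _SEPARATION_BETA))
    return {
        "beta0": b0,
        "beta1": b1,
        "se1": se1,
        "converged": converged,
        "degenerate": degenerate,
        "separated": separated,
    }


def grouped_linear(levels: np.ndarray, n_per_level: np.ndarray,
                   sum_y_per_level: np.ndarray, sum_y: float, sum_y2: float):
    """Batched simple-regression OLS from per-level sufficient statistics.

    The response is shared across SNPs (|y_i - y_j| over the same pair set),
    so only the per-level pair counts and per-level response sums vary by
    SNP.  Returns ``beta0``, ``beta1``, ``se1``, ``df``, ``degenerate``.
    """
    x = np.asarray(levels, dtype=float)
    N = np.asarray(n_per_level, dtype=float)
    Sy_l = np.asarray(sum_y_per_level, dtype=float)
    n = N.sum(axis=1)
    Sx = N @ x
    Sxx = N @ (x * x)
    Sxy = (Sy_l * x).sum(axis=1)
    den = n * Sxx - Sx * Sx
    degenerate = den <= 1e-12
    den_safe = np.where(degenerate, 1.0, den)
    b1 = (n * Sxy - Sx * sum_y) / den_safe
    b0 = (sum_y - b1 * Sx) / n
    rss = sum_y2 - b0 * sum_y - b1 * Sxy
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.clip(rss, 0.0, None) / np.maximum(df, 1)
        se1 = np.sqrt(sigma2 * n / den_safe)
    b1 = np.where(degenerate, np.nan, b1)
    se1 = np.where(degenerate, np.nan, se1)
    return {"beta0": b0, "beta1": b1, "se1": se1, "df": df, "degenerate": degenerate}
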