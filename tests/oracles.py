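"""Independent reference implementations used only by the tests.

These deliberately avoid the package's ser/em code paths: the
exhaustive enumerator marginalizes over all causal configurations of a
spike-and-slab prior directly, and the individual-level engine works
from raw (X, y) sufficient statistics with explicit sample-size
bookkeeping.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def exhaustive_pips(
    z: np.ndarray,
    R: np.ndarray,
    pi: np.ndarray,
    sigma2: np.ndarray,
) -> np.ndarray:
    """Exact PIPs by enumerating all 2^p causal configurations.

    Model: z_hat | config S ~ N(0, R + R[:,S] diag(sigma2_S) R[S,:]),
    prior P(S) = prod_{j in S} pi_j * prod_{j not in S} (1 - pi_j).
    """
    p = len(z)
    log_w = []
    subsets = []
    for mask in itertools.product([0, 1], repeat=p):
        S = np.flatnonzero(mask)
        cov = R + (R[:, S] * sigma2[S]) @ R[S, :] if len(S) else R.copy()
        ll = multivariate_normal.logpdf(z, mean=np.zeros(p), cov=cov,
                                        allow_singular=True)
        lp = np.sum(np.log(pi[S])) if len(S) else 0.0
        notS = np.setdiff1d(np.arange(p), S)
        lp += np.sum(np.log1p(-pi[notS]))
        log_w.append(ll + lp)
        subsets.append(S)
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    pips = np.zeros(p)
    for weight, S in zip(w, subsets):
        pips[S] += weight
    return pips


def susie_individual(
    X: np.ndarray,
    y: np.ndarray,
    pi: np.ndarray,
    prior_var: np.ndarray,
    null_weight: float,
    L: int,
    residual_var: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> np.ndarray:
    """Sum-of-single-effects on raw individual-level data; returns PIPs.

    Standard Bayesian single-effect regression with explicit X'X
    diagonals and sample size, iterated over L effects on residualized
    X'y. Serves as the individual-level reference for the summary-
    statistic engine under the substitutions X'X -> R, X'y -> z-hat,
    y'y -> 1, n -> 1.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    d = np.diag(XtX)

    def ser(Xtr):
        s1_sq = 1.0 / (d / residual_var + 1.0 / prior_var)
        mu1 = (Xtr / residual_var) * s1_sq
        lbf = 0.5 * np.log(s1_sq / prior_var) + 0.5 * mu1**2 / s1_sq
        lw = np.where(pi > 0, np.log(np.where(pi > 0, pi, 1.0)) + lbf, -np.inf)
        lw_null = np.log(null_weight) if null_weight > 0 else -np.inf
        m = max(float(np.max(lw)), lw_null)
        w = np.exp(lw - m)
        denom = w.sum() + np.exp(lw_null - m)
        return w / denom, mu1

    alpha = np.zeros((L, p))
    b = np.zeros((L, p))
    for _ in range(max_iter):
        alpha_old = alpha.copy()
        for l in range(L):
            Xtr = Xty - XtX @ (b.sum(axis=0) - b[l])
            alpha[l], mu1 = ser(Xtr)
            b[l] = alpha[l] * mu1
        if np.max(np.abs(alpha - alpha_old)) < tol:
            break
    return 1.0 - np.prod(1.0 - alpha, axis=0)


def exhaustive_loglik(
    z: np.ndarray, R: np.ndarray, pi: np.ndarray, sigma2: np.ndarray
) -> float:
    """Observed-data log-likelihood of one region by full enumeration."""
    p = len(z)
    log_terms = []
    for mask in itertools.product([0, 1], repeat=p):
        S = np.flatnonzero(mask)
        cov = R + (R[:, S] * sigma2[S]) @ R[S, :] if len(S) else R.copy()
        ll = multivariate_normal.logpdf(z, mean=np.zeros(p), cov=cov,
                                        allow_singular=True)
        lp = np.sum(np.log(pi[S])) if len(S) else 0.0
        notS = np.setdiff1d(np.arange(p), S)
        lp += np.sum(np.log1p(-pi[notS]))
        log_terms.append(ll + lp)
    log_terms = np.array(log_terms)
    m = log_terms.max()
    return float(m + np.log(np.exp(log_terms - m).sum()))
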