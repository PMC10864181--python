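"""Sum-of-single-effects regression on summary statistics.

The engine works entirely on the z-score scale: marginal associations
z-hat with correlation matrix R, modelled as z-hat | z, R ~ N(Rz, R).
This is the sufficient-statistic form of a linear regression after the
substitutions X'X -> R, X'y -> z-hat, y'y -> 1, n -> 1, so residual
variance is fixed at 1 and prior effect variances are on the z scale.

Each single effect l picks at most one variable (or nothing, with
probability ``null_weight``); per-variable prior inclusion weights and
slab variances come from the group-level spike-and-slab prior and stay
fixed during fitting. Credible sets follow the usual coverage +
purity (min |r| > 0.5) convention.
"""
from __future__ import annotations

import logging

import numpy as np

from .types import AugmentedRegion, CredibleSet, SERPosterior, SERPrior, SusieFit

logger = logging.getLogger(__name__)


def normalize_prior(pi: np.ndarray, sigma2, eps: float = 1e-6) -> SERPrior:
    """Build an SERPrior with null weight 1 - sum(pi).

    If the group-level weights sum to >= 1 (pathological), they are
    rescaled to sum to 1 - eps so a null option always remains.
    """
    pi = np.asarray(pi, dtype=float)
    total = pi.sum()
    if total > 1.0:
        logger.info("prior inclusion weights sum to %g > 1; renormalizing",
                    total)
        pi = pi * (1.0 - eps) / total
        total = 1.0 - eps
    return SERPrior(pi=pi, sigma2=sigma2, null_weight=max(1.0 - total, 0.0))


def ser_rss(z_resid: np.ndarray, prior: SERPrior) -> SERPosterior:
    """Bayesian single-effect regression on (residualized) z-scores.

    For variable j with slab variance s2: the log Bayes factor against
    the null is  lbf_j = -log(1+s2)/2 + z_j^2 s2 / (2 (1+s2)),
    the posterior mean given inclusion  mu1_j = z_j s2/(1+s2)  and the
    posterior variance  s1_j^2 = s2/(1+s2). Inclusion probabilities are
    the prior weights reweighted by the Bayes factors, normalized jointly
    with the null option (BF = 1).
    """
    z = np.asarray(z_resid, dtype=float)
    s2 = prior.sigma2
    if prior.null_weight == 0.0 and np.all(prior.pi == 0):
        raise ValueError("all prior weights zero with no null option")
    shrink = s2 / (1.0 + s2)
    lbf = 0.5 * (-np.log1p(s2) + z * z * shrink)
    mu1 = z * shrink
    s1_sq = shrink.copy()

    # normalize alpha jointly with the null option, guarding overflow
    lw = np.where(prior.pi > 0, np.log(np.where(prior.pi > 0, prior.pi, 1.0)) + lbf,
                  -np.inf)
    lw_null = np.log(prior.null_weight) if prior.null_weight > 0 else -np.inf
    m = max(float(np.max(lw, initial=-np.inf)), lw_null)
    w = np.exp(lw - m)
    w_null = np.exp(lw_null - m)
    denom = w.sum() + w_null
    alpha = w / denom
    alpha_null = float(w_null / denom)
    # log of the model BF: weighted average of per-variable BFs + null
    lbf_total = float(m + np.log(denom))
    return SERPosterior(
        alpha=alpha, alpha_null=alpha_null, mu1=mu1, s1_sq=s1_sq,
        lbf=lbf, lbf_total=lbf_total,
    )


def _elbo(
    z: np.ndarray,
    R: np.ndarray,
    alpha: np.ndarray,
    mu1: np.ndarray,
    s1_sq: np.ndarray,
    lbf_total: np.ndarray,
    z_resid_per_effect: np.ndarray,
) -> float:
    """Variational objective on the z-score scale (y'y -> 1, n -> 1).

    Uses the standard sum-of-single-effects identity: the KL term of each
    effect is recovered from its Bayes factor and the expected
    log-likelihood of its residualized problem, so only sufficient
    statistics are needed.
    """
    L, p = alpha.shape
    b = alpha * mu1  # (L, p) posterior mean effects
    b_total = b.sum(axis=0)
    m2 = alpha * (mu1**2 + s1_sq)  # E[b^2], diagonal d_j = R_jj = 1
    # E ||y - X b||^2 with sufficient statistics
    erss = (
        1.0
        - 2.0 * float(b_total @ z)
        + float(b_total @ R @ b_total)
        - float(np.einsum("lp,pq,lq->", b, R, b))
        + float(m2.sum())
    )
    eloglik = -0.5 * np.log(2 * np.pi) - 0.5 * erss
    kl = 0.0
    for l in range(L):
        zr = z_resid_per_effect[l]
        # E_q log p(y_resid | b_l) - lbf_l - loglik0(y_resid); y'y terms cancel
        e_ll = -0.5 * np.log(2 * np.pi) - 0.5 * (
            1.0 - 2.0 * float(b[l] @ zr) + float(m2[l].sum())
        )
        ll0 = -0.5 * np.log(2 * np.pi) - 0.5 * 1.0
        kl += e_ll - lbf_total[l] - ll0
    return eloglik - kl


def susie_rss(
    region: AugmentedRegion,
    prior: SERPrior,
    L: int = 5,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> SusieFit:
    """Iterative Bayesian stepwise selection with L single effects.

    Each pass residualizes the z-vector against the other effects'
    posterior means through R, re-solves the single-effect problem, and
    repeats until the largest change in any inclusion probability falls
    below ``tol``. Deterministic given its inputs.
    """
    z = region.z
    R = region.corr
    p = len(z)
    if len(prior.pi) != p:
        raise ValueError("prior not dimensioned to region variables")
    L = max(1, int(L))

    alpha = np.zeros((L, p))
    mu1 = np.zeros((L, p))
    s1_sq = np.zeros((L, p))
    alpha_null = np.ones(L)
    lbf_total = np.zeros(L)
    b = np.zeros((L, p))  # alpha * mu1 per effect
    z_resid_store = np.tile(z, (L, 1))
    elbo_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha_old = alpha.copy()
        b_total = b.sum(axis=0)
        Rb_total = R @ b_total
        for l in range(L):
            z_resid = z - (Rb_total - R @ b[l])
            post = ser_rss(z_resid, prior)
            Rb_total -= R @ b[l]
            alpha[l] = post.alpha
            mu1[l] = post.mu1
            s1_sq[l] = post.s1_sq
            alpha_null[l] = post.alpha_null
            lbf_total[l] = post.lbf_total
            b[l] = post.alpha * post.mu1
            z_resid_store[l] = z_resid
            Rb_total += R @ b[l]
        elbo_path.append(
            _elbo(z, R, alpha, mu1, s1_sq, lbf_total, z_resid_store)
        )
        if np.max(np.abs(alpha - alpha_old)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("region %s: susie_rss did not converge in %d iterations",
                       region.region_id, max_iter)
    return SusieFit(
        region_id=region.region_id,
        variable_ids=list(region.variable_ids),
        group_labels=region.group_labels,
        L=L,
        alpha=alpha,
        alpha_null=alpha_null,
        mu1=mu1,
        s1_sq=s1_sq,
        lbf_total=lbf_total,
        converged=converged,
        n_iter=it,
        elbo=np.asarray(elbo_path),
    )


def credible_sets(
    fit: SusieFit,
    corr: np.ndarray,
    coverage: float = 0.95,
    purity_threshold: float = 0.5,
) -> list[CredibleSet]:
    """Level-``coverage`` credible sets with purity filtering.

    For each effect, the smallest set of variables (by descending
    inclusion probability) whose cumulative probability reaches
    ``coverage``; a set is reported only when all member pairs are in
    strong LD (min |r| > ``purity_threshold``). Duplicate sets are
    dropped. Effects whose posterior is mostly on the null option are
    skipped.
    """
    sets: list[CredibleSet] = []
    seen = set()
    for l in range(fit.L):
        a = fit.alpha[l]
        total = a.sum()
        if total < coverage:  # effect is mostly null; no set at this coverage
            continue
        order = np.argsort(-a, kind="stable")
        csum = np.cumsum(a[order])
        k = int(np.searchsorted(csum, coverage) + 1)
        idx = np.sort(order[:k])
        sub = np.abs(corr[np.ix_(idx, idx)])
        purity = float(sub.min()) if len(idx) else 1.0
        if purity <= purity_threshold:
            continue
        members = tuple(fit.variable_ids[i] for i in idx)
        if members in seen:
            continue
        seen.add(members)
        sets.append(
            CredibleSet(
                members=list(members),
                coverage=float(csum[k - 1]),
                purity=purity,
                cs_id=f"{fit.region_id}:L{l + 1}",
            )
        )
    return sets
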