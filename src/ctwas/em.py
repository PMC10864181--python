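"""Empirical-Bayes estimation of the group-level spike-and-slab prior.

The four parameters theta = (pi_gene, pi_variant, sigma2_gene,
sigma2_variant) are estimated by maximum likelihood with an EM
algorithm. In the E-step every region is fine-mapped under a single
causal effect (L = 1), which gives each variable an inclusion
probability alpha_j and a posterior second moment tau2_j of its effect.
The M-step then sets each group's inclusion probability to the average
alpha over the group and its slab variance to the alpha-weighted average
of tau2 — both pooled across all regions.

Estimation runs on the thinned variant set; fine-mapping later revisits
every region, including any skipped here for size.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ser import normalize_prior, ser_rss
from .types import AugmentedRegion, GroupPriorEstimate

logger = logging.getLogger(__name__)

#: expected number of causal variables used to seed the initial pi
INIT_EXPECTED_CAUSAL = 50.0
#: initial slab variance on the z-score scale
INIT_SIGMA2 = 50.0
#: slab variances beyond this indicate divergence
SIGMA2_DIVERGENCE = 1e8


def region_prior(region: AugmentedRegion, theta: GroupPriorEstimate):
    """Per-variable SER prior for a region under group parameters theta."""
    is_gene = region.is_gene
    pi = np.where(is_gene, theta.pi_gene, theta.pi_variant)
    sigma2 = np.where(is_gene, theta.sigma2_gene, theta.sigma2_variant)
    return normalize_prior(pi, sigma2)


def e_step_region(
    region: AugmentedRegion, theta: GroupPriorEstimate
) -> tuple[np.ndarray, np.ndarray]:
    """Single-effect posterior (alpha_j, tau2_j) for one region.

    tau2_j = mu1_j^2 + s1_j^2 is the posterior second moment of the
    effect given inclusion.
    """
    if theta.pi_gene == 0 and theta.pi_variant == 0:
        raise ValueError("degenerate prior: both group probabilities are zero")
    prior = region_prior(region, theta)
    post = ser_rss(region.z, prior)
    tau2 = post.mu1**2 + post.s1_sq
    return post.alpha, tau2


def m_step(
    alphas: list[np.ndarray],
    tau2s: list[np.ndarray],
    labels: list[np.ndarray],
    previous: GroupPriorEstimate | None = None,
) -> GroupPriorEstimate:
    """Update group parameters from pooled E-step quantities.

    pi_k is the mean alpha over the group; sigma2_k the alpha-weighted
    mean of tau2. A group with zero posterior mass keeps its previous
    sigma2 (logged).
    """
    alpha = np.concatenate(alphas)
    tau2 = np.concatenate(tau2s)
    lab = np.concatenate(labels)
    out = {}
    sizes = {}
    for group in ("gene", "variant"):
        sel = lab == group
        sizes[group] = int(sel.sum())
        if sizes[group] == 0:
            # a variant-only (or gene-only) analysis: the absent group
            # keeps a zero prior
            logger.info("m_step: no variables in group %s", group)
            out[f"pi_{group}"] = 0.0
            out[f"sigma2_{group}"] = float(
                getattr(previous, f"sigma2_{group}") if previous is not None
                else INIT_SIGMA2
            )
            continue
        a = alpha[sel]
        mass = a.sum()
        out[f"pi_{group}"] = float(mass / sizes[group])
        if mass > 0:
            out[f"sigma2_{group}"] = float((a * tau2[sel]).sum() / mass)
        else:
            carried = (
                getattr(previous, f"sigma2_{group}") if previous is not None
                else INIT_SIGMA2
            )
            logger.info("m_step: zero posterior mass in group %s; sigma2 "
                        "carried over", group)
            out[f"sigma2_{group}"] = float(carried)
    return GroupPriorEstimate(group_sizes=sizes, **out)


def initialize_priors(regions: list[AugmentedRegion]) -> GroupPriorEstimate:
    """Default starting point: a flat prior expecting ~50 causal variables
    among all variables present, same for both groups, slab variance 50."""
    p_total = sum(r.n_variables for r in regions)
    pi0 = min(INIT_EXPECTED_CAUSAL / max(p_total, 1), 0.1)
    sizes = {
        "gene": int(sum((r.is_gene).sum() for r in regions)),
        "variant": int(sum((~r.is_gene).sum() for r in regions)),
    }
    return GroupPriorEstimate(
        pi_gene=pi0, pi_variant=pi0,
        sigma2_gene=INIT_SIGMA2, sigma2_variant=INIT_SIGMA2,
        group_sizes=sizes,
    )


def fit_priors(
    regions: list[AugmentedRegion],
    init: GroupPriorEstimate | None = None,
    n_iter: int = 30,
    estimation_cap: int | None = 10000,
) -> GroupPriorEstimate:
    """Run the EM over (thinned) regions for a fixed number of iterations.

    Regions with more than ``estimation_cap`` variables are skipped
    during estimation only. The returned estimate carries the full
    per-iteration trajectory. Deterministic given inputs.
    """
    used = [
        r for r in regions
        if estimation_cap is None or r.n_variables <= estimation_cap
    ]
    n_skipped = len(regions) - len(used)
    if n_skipped:
        logger.info("fit_priors: %d oversized regions skipped during EM",
                    n_skipped)
    if not used:
        raise ValueError("no regions available for parameter estimation")
    theta = init if init is not None else initialize_priors(used)
    labels = [r.group_labels for r in used]
    rows = []
    for t in range(n_iter):
        alphas, tau2s = [], []
        for r in used:
            a, tau2 = e_step_region(r, theta)
            alphas.append(a)
            tau2s.append(tau2)
        theta = m_step(alphas, tau2s, labels, previous=theta)
        if max(theta.sigma2_gene, theta.sigma2_variant) > SIGMA2_DIVERGENCE:
            raise RuntimeError(
                f"EM diverged at iteration {t + 1}: sigma2 exceeds "
                f"{SIGMA2_DIVERGENCE:g}"
            )
        rows.append(
            {
                "iteration": t + 1,
                "pi_gene": theta.pi_gene,
                "pi_variant": theta.pi_variant,
                "sigma2_gene": theta.sigma2_gene,
                "sigma2_variant": theta.sigma2_variant,
            }
        )
    theta.trajectory = pd.DataFrame(rows)
    return theta
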