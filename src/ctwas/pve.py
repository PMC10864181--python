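"""Proportion of phenotypic variance explained per variable group.

On the z-score scale, a causal variable's effect satisfies
beta = z / sqrt(n), so its expected contribution to trait variance is
sigma2_k / n and a group of |M_k| variables with inclusion probability
pi_k explains

    PVE_k = sigma2_k * pi_k * |M_k| / n.

The fraction of explained variance attributable to expression is
PVE_gene / (PVE_gene + PVE_variant).
"""
from __future__ import annotations

from .types import GroupPriorEstimate, PveReport


def group_pve(sigma2_k: float, pi_k: float, group_size: int, n: int) -> float:
    """PVE of one variable group from its prior parameters (z scale)."""
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    if sigma2_k < 0 or pi_k < 0 or group_size < 0:
        raise ValueError("inputs must be nonnegative")
    return sigma2_k * pi_k * group_size / n


def pve_report(theta: GroupPriorEstimate, n: int) -> PveReport:
    """Per-group PVE report from fitted prior parameters.

    ``theta.group_sizes`` must hold the variable counts the parameters
    were estimated on (genes; thinned variants when thinning was used).
    """
    return PveReport(
        pve_gene=group_pve(
            theta.sigma2_gene, theta.pi_gene, theta.group_sizes["gene"], n
        ),
        pve_variant=group_pve(
            theta.sigma2_variant, theta.pi_variant,
            theta.group_sizes["variant"], n,
        ),
        n_gwas=n,
    )
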