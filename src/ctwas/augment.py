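"""Expand variant-level summary statistics with imputed-gene variables.

A gene's imputed expression is the weighted sum of its eQTL genotypes,
so on the standardized scale its GWAS z-score and its correlation with
every other variable follow from the variant z-scores and the LD matrix:

    z_gene   = w' z_v / sqrt(w' R w)
    r(g, m)  = w' R e_m / sqrt(w' R w)
    r(g, h)  = w_g' R w_h / (sqrt(w_g' R w_g) sqrt(w_h' R w_h))

Imputation uncertainty in the expression model is ignored throughout.
"""
from __future__ import annotations

import logging
import pathlib

import numpy as np
import pandas as pd

from .types import AugmentedRegion, WeightModel

logger = logging.getLogger(__name__)

#: genes whose imputed-expression variance w'Rw falls below this are
#: dropped as degenerate
IMPUTATION_VARIANCE_FLOOR = 1e-10


class DegenerateImputation(Exception):
    """Imputed expression has (numerically) zero variance under the LD."""


def gene_z(w: np.ndarray, z_v: np.ndarray, R_v: np.ndarray) -> float:
    """z-score of a gene's standardized imputed expression.

    ``w`` are standardized-scale weights over the gene's model variants,
    ``z_v`` the harmonized variant z-scores and ``R_v`` the LD among the
    model variants.
    """
    w = np.asarray(w, dtype=float)
    var = float(w @ R_v @ w)
    if var <= IMPUTATION_VARIANCE_FLOOR:
        raise DegenerateImputation(f"imputed expression variance {var:g}")
    return float(w @ z_v) / np.sqrt(var)


def build_augmented(
    region_id: str,
    variant_table: pd.DataFrame,
    corr: np.ndarray,
    gene_models: list[WeightModel],
    n_gwas: int,
    variant_mask: np.ndarray | None = None,
    force_model_variants: bool = True,
) -> AugmentedRegion:
    """Build the joint (genes + variants) z-vector and correlation matrix.

    ``variant_table`` lists the region's variants (with ``z``) in the
    row order of ``corr``. ``variant_mask`` selects the variants to carry
    as explicit variables (thinning/cap); with ``force_model_variants``
    the eQTL variants of the region's genes are re-added on top of the
    mask so fine-mapping can weigh each gene against its own eQTLs
    (parameter estimation instead uses the pure thinned sample).
    Gene z-scores and correlations always use the full weight vectors
    regardless of the mask. Gene variables come first in the output
    ordering. Genes with degenerate imputation variance are dropped with
    a log message.

    The result is positive semidefinite by construction (it is D'RD for
    a full-rank-in-columns D); any negative eigenvalues introduced by
    floating-point noise are clipped at zero.
    """
    p_all = len(variant_table)
    if corr.shape != (p_all, p_all):
        raise ValueError("corr does not match variant_table")
    if variant_mask is None:
        variant_mask = np.ones(p_all, dtype=bool)
    variant_mask = variant_mask.copy()

    row_of = {vid: i for i, vid in enumerate(variant_table["variant_id"])}
    z_all = variant_table["z"].to_numpy(dtype=float)

    # weight matrix over all region variants, one column per retained gene
    kept_models: list[WeightModel] = []
    cols = []
    for m in gene_models:
        idx = np.array([row_of[v] for v in m.variant_ids], dtype=int)
        col = np.zeros(p_all)
        col[idx] = m.weights
        var = float(col @ corr @ col)
        if var <= IMPUTATION_VARIANCE_FLOOR:
            logger.warning("gene %s dropped: degenerate imputation variance %g",
                           m.gene_id, var)
            continue
        kept_models.append(m)
        cols.append(col / np.sqrt(var))
        if force_model_variants:
            variant_mask[idx] = True

    keep_idx = np.flatnonzero(variant_mask)
    n_g = len(kept_models)
    W = np.column_stack(cols) if n_g else np.empty((p_all, 0))

    z_genes = W.T @ z_all
    RW = corr @ W  # (p_all, n_g)
    gg = W.T @ RW
    gv = RW[keep_idx].T  # (n_g, n_kept)
    vv = corr[np.ix_(keep_idx, keep_idx)]

    p = n_g + len(keep_idx)
    A = np.empty((p, p))
    A[:n_g, :n_g] = gg
    A[:n_g, n_g:] = gv
    A[n_g:, :n_g] = gv.T
    A[n_g:, n_g:] = vv
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A[:n_g, :n_g], 1.0)

    if p:
        evals = np.linalg.eigvalsh(A)
        if evals[0] < -1e-10:
            w_e, v_e = np.linalg.eigh(A)
            A = (v_e * np.clip(w_e, 0.0, None)) @ v_e.T
            A = 0.5 * (A + A.T)
            logger.info("region %s: clipped %d negative eigenvalues (min %g)",
                        region_id, int((w_e < 0).sum()), evals[0])

    variable_ids = [m.gene_id for m in kept_models] + list(
        variant_table["variant_id"].to_numpy()[keep_idx]
    )
    labels = np.array(
        ["gene"] * n_g + ["variant"] * len(keep_idx), dtype=object
    )
    z = np.concatenate([z_genes, z_all[keep_idx]])
    return AugmentedRegion(
        region_id=region_id,
        variable_ids=variable_ids,
        group_labels=labels,
        z=z,
        corr=A,
        n_gwas=n_gwas,
    )


def save_augmented(region: AugmentedRegion, path: str | pathlib.Path) -> None:
    np.savez_compressed(
        path,
        region_id=np.array(region.region_id),
        variable_ids=np.array(region.variable_ids, dtype=object),
        group_labels=region.group_labels,
        z=region.z,
        corr=region.corr,
        n_gwas=np.array(region.n_gwas),
    )


def load_augmented(path: str | pathlib.Path) -> AugmentedRegion:
    d = np.load(path, allow_pickle=True)
    return AugmentedRegion(
        region_id=str(d["region_id"]),
        variable_ids=list(d["variable_ids"]),
        group_labels=d["group_labels"],
        z=d["z"],
        corr=d["corr"],
        n_gwas=int(d["n_gwas"]),
    )
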