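"""Allele harmonization of GWAS z-scores and eQTL weights to an LD reference.

Three datasets must agree on which allele is "alt" at every variant: the
GWAS summary statistics, the expression prediction models, and the LD
reference. Relative to the reference a variant can be

* ``match``    — same ordered (ref, alt) pair, nothing to do;
* ``flipped``  — ref/alt swapped: the z-score or weight changes sign;
* ``switched`` — reported on the opposite strand (both alleles
  complemented): the sign is already consistent, nothing to do;
* ``ambiguous`` — the two alleles are themselves a complementary pair
  (A/T or G/C), so a flip cannot be distinguished from a strand switch;
* ``incompatible`` — the alleles cannot be reconciled; the variant is
  dropped.

Ambiguous z-scores can optionally be sign-corrected by imputing the
expected z from unambiguous variants in the same LD block; ambiguous
weights are resolved by comparing correlation sums between the model's
own LD and the reference LD.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import LDBlockMatrix, WeightModel, validate_allele

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def classify_allele_pair(
    ref_alleles: tuple[str, str], other_alleles: tuple[str, str]
) -> str:
    """Classify an allele pair against the LD reference's ordered pair.

    Returns one of ``match``, ``flipped``, ``switched``, ``ambiguous``,
    ``incompatible``. A reversed-complement pair (flip on the opposite
    strand) is reported as ``flipped``, since the sign correction is the
    same.
    """
    a, b = (validate_allele(x) for x in ref_alleles)
    c, d = (validate_allele(x) for x in other_alleles)
    if a == b or c == d:
        raise ValueError("ref and alt allele must differ")
    ca, cb = _COMPLEMENT[a], _COMPLEMENT[b]
    compatible = (c, d) in {(a, b), (b, a), (ca, cb), (cb, ca)}
    if not compatible:
        return "incompatible"
    if b == ca:  # complementary pair (A/T or G/C): flip vs switch undecidable
        return "ambiguous"
    if (c, d) == (a, b):
        return "match"
    if (c, d) == (b, a):
        return "flipped"
    if (c, d) == (ca, cb):
        return "switched"
    return "flipped"  # reversed complement: flipped on the other strand


def _classify_table(
    df: pd.DataFrame, ld_index: pd.DataFrame
) -> pd.DataFrame:
    """Join a variant table with the LD reference on (chrom, pos) and add a
    ``status`` column; variants absent from the reference get ``missing``."""
    merged = df.merge(
        ld_index,
        on=["chrom", "pos"],
        how="left",
        suffixes=("", "_ld"),
    )
    status = []
    for ref, alt, ref_ld, alt_ld in zip(
        merged["ref"], merged["alt"], merged["ref_ld"], merged["alt_ld"]
    ):
        if pd.isna(ref_ld):
            status.append("missing")
        else:
            status.append(classify_allele_pair((ref_ld, alt_ld), (ref, alt)))
    merged["status"] = status
    return merged


def ld_reference_index(ld_blocks: list[LDBlockMatrix]) -> pd.DataFrame:
    """Flat lookup table of the LD reference: one row per variant with its
    block id and within-block index."""
    rows = []
    for blk in ld_blocks:
        t = blk.variants.copy()
        t["block_id"] = blk.block_id
        t["block_index"] = np.arange(len(t))
        rows.append(t)
    idx = pd.concat(rows, ignore_index=True)
    return idx.rename(
        columns={
            "variant_id": "variant_id_ld",
            "ref": "ref_ld",
            "alt": "alt_ld",
        }
    )[["chrom", "pos", "variant_id_ld", "ref_ld", "alt_ld", "block_id", "block_index"]]


def _impute_z_sign(
    z_obs: float,
    amb_idx: int,
    unamb_idx: np.ndarray,
    z_unamb: np.ndarray,
    corr: np.ndarray,
    ridge: float,
) -> float:
    """Expected z of one ambiguous variant from unambiguous block-mates.

    Conditional mean under z ~ N(0, R): R_as (R_ss + ridge*I)^-1 z_s.
    Returns the observed z with its sign replaced by the imputed sign
    (magnitude untouched); zero imputed mean leaves the sign alone.
    """
    if len(unamb_idx) == 0:
        return z_obs
    r_as = corr[amb_idx, unamb_idx]
    r_ss = corr[np.ix_(unamb_idx, unamb_idx)] + ridge * np.eye(len(unamb_idx))
    z_hat = float(r_as @ np.linalg.solve(r_ss, z_unamb))
    if z_hat == 0.0 or np.sign(z_hat) == np.sign(z_obs):
        return z_obs
    return -z_obs


def harmonize_z(
    gwas: pd.DataFrame,
    ld_blocks: list[LDBlockMatrix],
    resolve_ambiguous: bool = False,
    ridge: float = 0.01,
) -> pd.DataFrame:
    """Harmonize GWAS z-scores to the LD reference.

    Parameters
    ----------
    gwas
        Variant table with columns variant_id, chrom, pos, ref, alt, z,
        n_gwas.
    resolve_ambiguous
        When True, the sign of each strand-ambiguous variant's z is set to
        the sign of its LD-imputed conditional mean given the unambiguous
        variants of the block (use with out-of-sample LD; with in-sample
        LD ambiguous variants are already consistent and pass through).

    Returns the harmonized table, re-keyed to the LD reference's variant
    ids and allele order, with block assignment columns. Variants missing
    from or incompatible with the reference are dropped (counts logged).
    Idempotent: harmonized output classifies as ``match`` throughout.
    """
    merged = _classify_table(gwas, ld_reference_index(ld_blocks))
    n_missing = int((merged["status"] == "missing").sum())
    n_incomp = int((merged["status"] == "incompatible").sum())
    if n_missing or n_incomp:
        logger.info(
            "harmonize_z: dropped %d variants absent from LD reference, "
            "%d with incompatible alleles", n_missing, n_incomp,
        )
    keep = merged[~merged["status"].isin(["missing", "incompatible"])].copy()
    keep["z"] = np.where(keep["status"] == "flipped", -keep["z"], keep["z"])

    if resolve_ambiguous and (keep["status"] == "ambiguous").any():
        block_corr = {b.block_id: b.corr for b in ld_blocks}
        for block_id, sub in keep.groupby("block_id", sort=False):
            amb = sub[sub["status"] == "ambiguous"]
            if amb.empty:
                continue
            unamb = sub[sub["status"] != "ambiguous"]
            corr = block_corr[block_id]
            u_idx = unamb["block_index"].to_numpy(dtype=int)
            z_u = unamb["z"].to_numpy(dtype=float)
            for row in amb.itertuples():
                keep.loc[row.Index, "z"] = _impute_z_sign(
                    row.z, int(row.block_index), u_idx, z_u, corr, ridge
                )

    # adopt the LD reference's allele orientation so output is canonical
    out = keep.copy()
    out["variant_id"] = out["variant_id_ld"]
    out["ref"] = out["ref_ld"]
    out["alt"] = out["alt_ld"]
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "z", "n_gwas",
            "block_id", "block_index"]
    return out[cols].reset_index(drop=True)


class ModelRejected(Exception):
    """A weight model cannot be harmonized and is excluded from analysis."""


def harmonize_weights(
    model: WeightModel,
    ld_blocks: list[LDBlockMatrix],
    model_ld_cov: pd.DataFrame | None = None,
) -> WeightModel:
    """Harmonize one gene's eQTL weights to the LD reference.

    Flipped weights are negated; switched weights pass through. Each
    strand-ambiguous variant with at least one unambiguous partner in the
    model has its weight sign reversed iff the sum of its correlations
    with the unambiguous partners disagrees in sign between the model's
    own LD (``model_ld_cov``: columns VAR1, VAR2, COV) and the reference
    LD; a zero reference correlation sum zeroes the weight. A model whose
    single variant is ambiguous is kept unchanged; a model with two or
    more ambiguous variants and no unambiguous ones raises
    :class:`ModelRejected`, as would an empty post-intersection model.
    """
    tbl = model.variants.copy()
    tbl["weight"] = model.weights
    merged = _classify_table(tbl, ld_reference_index(ld_blocks))
    keep = merged[~merged["status"].isin(["missing", "incompatible"])].copy()
    n_drop = len(merged) - len(keep)
    if n_drop:
        logger.info("harmonize_weights[%s]: dropped %d variants",
                    model.gene_id, n_drop)
    if keep.empty:
        raise ModelRejected(
            f"{model.gene_id}: no variants left after LD-reference intersection"
        )
    keep["weight"] = np.where(
        keep["status"] == "flipped", -keep["weight"], keep["weight"]
    )

    amb_mask = (keep["status"] == "ambiguous").to_numpy()
    n_amb, n_unamb = int(amb_mask.sum()), int((~amb_mask).sum())
    if n_amb >= 2 and n_unamb == 0:
        raise ModelRejected(
            f"{model.gene_id}: {n_amb} ambiguous variants and no unambiguous "
            "ones; gene z-score could be wrong in sign and magnitude"
        )
    if n_amb and n_unamb:
        keep = _resolve_ambiguous_weights(model, keep, ld_blocks, model_ld_cov)
    # single ambiguous variant without partners: sign left unchanged

    out_variants = keep.copy()
    out_variants["variant_id"] = out_variants["variant_id_ld"]
    out_variants["ref"] = out_variants["ref_ld"]
    out_variants["alt"] = out_variants["alt_ld"]
    cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    return WeightModel(
        gene_id=model.gene_id,
        chrom=model.chrom,
        tss_pos=model.tss_pos,
        variants=out_variants[cols].reset_index(drop=True),
        weights=out_variants["weight"].to_numpy(dtype=float),
        scale=model.scale,
    )


def _resolve_ambiguous_weights(
    model: WeightModel,
    keep: pd.DataFrame,
    ld_blocks: list[LDBlockMatrix],
    model_ld_cov: pd.DataFrame | None,
) -> pd.DataFrame:
    block_corr = {b.block_id: b.corr for b in ld_blocks}
    cov_lookup: dict[tuple[str, str], float] = {}
    if model_ld_cov is not None:
        for r in model_ld_cov.itertuples():
            cov_lookup[(r.VAR1, r.VAR2)] = float(r.COV)
            cov_lookup[(r.VAR2, r.VAR1)] = float(r.COV)

    unamb = keep[keep["status"] != "ambiguous"]
    for row in keep[keep["status"] == "ambiguous"].itertuples():
        partners = unamb[unamb["block_id"] == row.block_id]
        if partners.empty:
            continue
        corr = block_corr[row.block_id]
        ref_sum = float(
            corr[int(row.block_index), partners["block_index"].to_numpy(int)].sum()
        )
        if ref_sum == 0.0:
            keep.loc[row.Index, "weight"] = 0.0
            continue
        if not cov_lookup:
            continue  # no model-side LD: nothing to compare, sign kept
        model_sum = sum(
            cov_lookup.get((row.variant_id, vid), 0.0)
            for vid in partners["variant_id"]
        )
        if model_sum != 0.0 and np.sign(model_sum) != np.sign(ref_sum):
            keep.loc[row.Index, "weight"] = -keep.loc[row.Index, "weight"]
    return keep


def standardize_weights(
    model: WeightModel, genotype_sd: np.ndarray
) -> WeightModel:
    """Convert per-allele weights to the standardized-genotype scale.

    Multiplies each weight by the genotype standard deviation from the LD
    reference (sqrt(2*maf*(1-maf)) under Hardy-Weinberg equilibrium),
    so that w * G_std contributes the same variance as the per-allele
    weight applied to the raw dosage. Variants with zero or missing
    genotype variance are dropped.
    """
    if model.scale != "per_allele":
        raise ValueError("standardize_weights expects a per_allele model")
    sd = np.asarray(genotype_sd, dtype=float)
    if sd.shape != model.weights.shape:
        raise ValueError("genotype_sd must align with model variants")
    ok = np.isfinite(sd) & (sd > 0)
    if not ok.all():
        logger.info(
            "standardize_weights[%s]: dropped %d variants with zero/missing "
            "genotype variance", model.gene_id, int((~ok).sum()),
        )
    if not ok.any():
        raise ModelRejected(
            f"{model.gene_id}: no variants with positive genotype variance"
        )
    return WeightModel(
        gene_id=model.gene_id,
        chrom=model.chrom,
        tss_pos=model.tss_pos,
        variants=model.variants[ok].reset_index(drop=True),
        weights=model.weights[ok] * sd[ok],
        scale="standardized",
    )
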