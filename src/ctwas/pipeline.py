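"""End-to-end orchestration: harmonize -> assemble -> expand -> EM -> two-pass
fine-mapping -> results table.

The two fine-mapping passes are a screening pass on thinned variants
(plus all genes and their eQTLs) and a rescue pass that refits any
region whose maximum gene PIP exceeds a threshold using the full (or
capped) variant set, so that gene signals surviving screening are
re-examined against every local variant before being reported.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import build_augmented
from .em import fit_priors, region_prior
from .harmonize import ModelRejected, harmonize_weights, harmonize_z, standardize_weights
from .pve import pve_report
from .regions import (
    RegionIndex,
    assemble_region_ld,
    assign_and_merge,
    cap_variants,
    thin_variants,
)
from .ser import credible_sets, susie_rss
from .types import (
    AugmentedRegion,
    GroupPriorEstimate,
    LDBlockMatrix,
    PveReport,
    RegionDefinition,
    SusieFit,
    WeightModel,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of a run, with the method's defaults."""

    thin: float = 0.1                 # fraction of variants kept in EM/screening
    L: int = 5                        # single effects per region in fine-mapping
    em_iterations: int = 30           # EM steps, each region at L = 1
    estimation_cap: int = 10000       # skip larger regions during EM only
    rescue_threshold: float = 0.8     # max gene PIP triggering the full refit
    max_variants: int = 20000         # variant cap in the rescue pass
    coverage: float = 0.95
    purity_threshold: float = 0.5
    pip_threshold: float = 0.8        # significance threshold on gene PIP
    resolve_ambiguous: bool = False
    tol: float = 1e-3
    max_iter: int = 100
    seed: int = 0


def _region_seed(seed: int, region_id: str, salt: int = 0) -> int:
    digest = zlib.crc32(region_id.encode())  # stable across processes
    h = np.random.SeedSequence([seed, salt, digest])
    return int(h.generate_state(1)[0] % (2**31))


def prepare_inputs(
    gwas: pd.DataFrame,
    weight_models: list[WeightModel],
    ld_blocks: list[LDBlockMatrix],
    blocks: list[RegionDefinition],
    model_ld_cov: pd.DataFrame | None = None,
    resolve_ambiguous: bool = False,
) -> tuple[pd.DataFrame, list[WeightModel], RegionIndex]:
    """Harmonize everything to the LD reference and build the region index.

    Weight models are harmonized (rejections logged), converted to the
    standardized scale where needed, and restricted to variants with a
    GWAS z-score; genes left without supported variants are dropped.
    """
    harmonized = harmonize_z(gwas, ld_blocks, resolve_ambiguous=resolve_ambiguous)
    maf_lookup = {}
    for blk in ld_blocks:
        if "maf" in blk.variants:
            maf_lookup.update(zip(blk.variants["variant_id"],
                                  blk.variants["maf"]))
    have_z = set(harmonized["variant_id"])
    kept_models = []
    n_rejected = 0
    for m in weight_models:
        try:
            hm = harmonize_weights(m, ld_blocks, model_ld_cov=model_ld_cov)
            if hm.scale == "per_allele":
                maf = np.array(
                    [maf_lookup.get(v, np.nan) for v in hm.variant_ids]
                )
                sd = np.sqrt(2.0 * maf * (1.0 - maf))
                hm = standardize_weights(hm, sd)
            ok = hm.variants["variant_id"].isin(have_z).to_numpy()
            if not ok.any():
                raise ModelRejected(
                    f"{hm.gene_id}: no model variant has a GWAS z-score"
                )
            if not ok.all():
                hm = WeightModel(
                    gene_id=hm.gene_id, chrom=hm.chrom, tss_pos=hm.tss_pos,
                    variants=hm.variants[ok].reset_index(drop=True),
                    weights=hm.weights[ok], scale=hm.scale,
                )
            kept_models.append(hm)
        except ModelRejected as exc:
            logger.info("weight model rejected: %s", exc)
            n_rejected += 1
    if n_rejected:
        logger.info("prepare_inputs: %d weight models rejected", n_rejected)
    index = assign_and_merge(blocks, harmonized, kept_models)
    kept_models = [
        m for m in kept_models if m.gene_id not in set(index.rejected_genes)
    ]
    return harmonized, kept_models, index


def build_regions(
    index: RegionIndex,
    models: list[WeightModel],
    ld_blocks: list[LDBlockMatrix],
    n_gwas: int,
    thin: float = 0.1,
    seed: int = 0,
    force_model_variants: bool = True,
) -> dict[str, AugmentedRegion]:
    """Thinned augmented region per region id: genes + strided variants.

    With ``force_model_variants`` (the fine-mapping setting) the eQTLs
    of retained genes are added back on top of the stride; without it
    (the estimation setting) the variant set is the pure thinned sample,
    so the variant group stays a representative subsample of the genome.
    """
    block_map = {b.block_id: b for b in ld_blocks}
    models_by_region: dict[str, list[WeightModel]] = {}
    by_id = {m.gene_id: m for m in models}
    for rid, gene_ids in index.genes.items():
        models_by_region[rid] = [by_id[g] for g in gene_ids]
    out = {}
    for rid in index.region_ids():
        vtab = index.region_variants(rid)
        if vtab.empty:
            continue
        corr = assemble_region_ld(index.regions[rid], block_map)
        mask = thin_variants(vtab, keep_fraction=thin,
                             seed=_region_seed(seed, rid, salt=1))
        out[rid] = build_augmented(
            rid, vtab, corr, models_by_region.get(rid, []), n_gwas,
            variant_mask=mask, force_model_variants=force_model_variants,
        )
    return out


def screen_regions(
    regions: dict[str, AugmentedRegion],
    theta: GroupPriorEstimate,
    config: PipelineConfig,
) -> dict[str, SusieFit]:
    """Fine-map every region (L = 5 by default) with thinned variants.

    All regions are analyzed, including any skipped during parameter
    estimation. A failure in one region is isolated and logged rather
    than aborting the run.
    """
    fits = {}
    for rid, region in regions.items():
        try:
            fit = susie_rss(
                region, region_prior(region, theta), L=config.L,
                max_iter=config.max_iter, tol=config.tol,
            )
            fit.credible_sets = credible_sets(
                fit, region.corr, coverage=config.coverage,
                purity_threshold=config.purity_threshold,
            )
            fits[rid] = fit
        except Exception:
            logger.exception("region %s failed during screening; skipped", rid)
    return fits


def max_gene_pip(fit: SusieFit) -> float:
    pip = fit.pip
    gene_pips = pip[fit.group_labels == "gene"]
    return float(gene_pips.max()) if len(gene_pips) else 0.0


def rescue_regions(
    screen_fits: dict[str, SusieFit],
    index: RegionIndex,
    models: list[WeightModel],
    ld_blocks: list[LDBlockMatrix],
    theta: GroupPriorEstimate,
    n_gwas: int,
    config: PipelineConfig,
) -> tuple[dict[str, SusieFit], set[str], dict[str, AugmentedRegion]]:
    """Refit regions whose screening max gene PIP exceeds the threshold,
    using the full variant set (capped at ``max_variants``)."""
    block_map = {b.block_id: b for b in ld_blocks}
    by_id = {m.gene_id: m for m in models}
    final = dict(screen_fits)
    rescued: set[str] = set()
    full_regions: dict[str, AugmentedRegion] = {}
    for rid, fit in screen_fits.items():
        if max_gene_pip(fit) <= config.rescue_threshold:
            continue
        vtab = index.region_variants(rid)
        corr = assemble_region_ld(index.regions[rid], block_map)
        mask = cap_variants(vtab, max_variants=config.max_variants,
                            seed=_region_seed(config.seed, rid, salt=2))
        region = build_augmented(
            rid, vtab, corr,
            [by_id[g] for g in index.genes.get(rid, [])],
            n_gwas, variant_mask=mask,
        )
        refit = susie_rss(
            region, region_prior(region, theta), L=config.L,
            max_iter=config.max_iter, tol=config.tol,
        )
        refit.credible_sets = credible_sets(
            refit, region.corr, coverage=config.coverage,
            purity_threshold=config.purity_threshold,
        )
        final[rid] = refit
        rescued.add(rid)
        full_regions[rid] = region
    logger.info("rescue pass refit %d of %d regions", len(rescued),
                len(screen_fits))
    return final, rescued, full_regions


def results_table(
    fits: dict[str, SusieFit],
    regions: dict[str, AugmentedRegion],
    rescued: set[str],
    full_regions: dict[str, AugmentedRegion] | None = None,
) -> pd.DataFrame:
    """One row per variable: id, type, region, z, PIP, credible set."""
    rows = []
    for rid in sorted(fits):
        fit = fits[rid]
        region = (full_regions or {}).get(rid) if rid in rescued else None
        region = region or regions.get(rid)
        z_by_id = (
            dict(zip(region.variable_ids, region.z)) if region is not None
            and region.variable_ids == fit.variable_ids else None
        )
        cs_of = {}
        for cs in fit.credible_sets:
            for member in cs.members:
                cs_of[member] = cs.cs_id
        pip = fit.pip
        for j, vid in enumerate(fit.variable_ids):
            rows.append(
                {
                    "variable_id": vid,
                    "type": str(fit.group_labels[j]),
                    "region_id": rid,
                    "z": z_by_id[vid] if z_by_id else np.nan,
                    "PIP": float(pip[j]),
                    "credible_set_id": cs_of.get(vid, ""),
                    "in_rescue_pass": rid in rescued,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variable_id", "type", "region_id", "z", "PIP",
                 "credible_set_id", "in_rescue_pass"],
    )


@dataclass
class RunArtifacts:
    results: pd.DataFrame
    theta: GroupPriorEstimate
    pve: PveReport
    fits: dict[str, SusieFit]
    regions: dict[str, AugmentedRegion]
    index: RegionIndex
    models: list[WeightModel]
    rescued: set[str] = field(default_factory=set)


def run_ctwas(
    gwas: pd.DataFrame,
    weight_models: list[WeightModel],
    ld_blocks: list[LDBlockMatrix],
    blocks: list[RegionDefinition],
    config: PipelineConfig | None = None,
    model_ld_cov: pd.DataFrame | None = None,
) -> RunArtifacts:
    """Full run on in-memory inputs; deterministic given config.seed."""
    config = config or PipelineConfig()
    harmonized, models, index = prepare_inputs(
        gwas, weight_models, ld_blocks, blocks,
        model_ld_cov=model_ld_cov,
        resolve_ambiguous=config.resolve_ambiguous,
    )
    if harmonized.empty:
        raise ValueError("no variants left after harmonization")
    n_gwas = int(harmonized["n_gwas"].median())
    # estimation pass: pure thinned sample, so that the per-variant
    # inclusion estimate transfers to the full variant set
    em_regions = build_regions(index, models, ld_blocks, n_gwas,
                               thin=config.thin, seed=config.seed,
                               force_model_variants=False)
    theta = fit_priors(
        list(em_regions.values()), n_iter=config.em_iterations,
        estimation_cap=config.estimation_cap,
    )
    # report/PVE bookkeeping: the prior applies per variable of the full
    # analyzed sets (genes are never thinned)
    theta.group_sizes = {
        "gene": len(models),
        "variant": int(len(harmonized)),
    }
    regions = build_regions(index, models, ld_blocks, n_gwas,
                            thin=config.thin, seed=config.seed,
                            force_model_variants=True)
    screen = screen_regions(regions, theta, config)
    final, rescued, full_regions = rescue_regions(
        screen, index, models, ld_blocks, theta, n_gwas, config
    )
    results = results_table(final, regions, rescued, full_regions=full_regions)
    pve = pve_report(theta, n_gwas)
    return RunArtifacts(
        results=results, theta=theta, pve=pve, fits=final, regions=regions,
        index=index, models=models, rescued=rescued,
    )
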