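"""Partition the genome into analysis regions and manage variant subsets.

LD blocks are treated as approximately independent. A gene belongs to
the block containing all of its eQTLs; when a prediction model spans
several blocks those blocks are merged (transitively) into one region.
Within a region, variants can be thinned to a deterministic stride for
parameter estimation and capped at a maximum count for the final
fine-mapping pass.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .types import LDBlockMatrix, RegionDefinition, WeightModel

logger = logging.getLogger(__name__)


@dataclass
class RegionIndex:
    """Mapping of every analyzed variant and gene to exactly one region."""

    regions: dict[str, RegionDefinition]
    variants: pd.DataFrame  # harmonized variant table + region_id column
    genes: dict[str, list[str]] = field(default_factory=dict)  # region -> genes
    rejected_genes: list[str] = field(default_factory=list)

    def region_variants(self, region_id: str) -> pd.DataFrame:
        sub = self.variants[self.variants["region_id"] == region_id]
        return sub.sort_values(["block_id", "block_index"]).reset_index(drop=True)

    def region_ids(self) -> list[str]:
        return sorted(self.regions)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice: lexicographically smallest id
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def assign_and_merge(
    blocks: list[RegionDefinition],
    variants: pd.DataFrame,
    gene_models: list[WeightModel],
) -> RegionIndex:
    """Assign genes to LD blocks and merge blocks spanned by any gene.

    ``variants`` is the harmonized variant table carrying ``block_id``
    (and ``block_index``). Merging is a transitive closure: if gene A
    spans blocks 1-2 and gene B spans 2-3, one region {1,2,3} results.
    The output regions partition the variants exactly. Genes whose model
    variants sit on two chromosomes, or are missing from ``variants``,
    are rejected (logged) rather than raising.
    """
    block_map = {b.region_id: b for b in blocks}
    uf = _UnionFind(block_map)
    var_to_block = dict(zip(variants["variant_id"], variants["block_id"]))

    gene_blocks: dict[str, set[str]] = {}
    rejected = []
    for m in gene_models:
        chroms = set(m.variants["chrom"])
        if len(chroms) > 1:
            logger.warning("gene %s spans chromosomes %s; rejected",
                           m.gene_id, sorted(chroms))
            rejected.append(m.gene_id)
            continue
        spanned = {var_to_block.get(v) for v in m.variant_ids}
        if None in spanned:
            logger.warning("gene %s has model variants outside the analyzed "
                           "set; rejected", m.gene_id)
            rejected.append(m.gene_id)
            continue
        gene_blocks[m.gene_id] = spanned  # type: ignore[assignment]
        first = next(iter(spanned))
        for b in spanned:
            uf.union(first, b)

    # group blocks by union-find root
    members: dict[str, list[str]] = {}
    for bid in block_map:
        members.setdefault(uf.find(bid), []).append(bid)

    regions: dict[str, RegionDefinition] = {}
    block_to_region: dict[str, str] = {}
    for root, bids in members.items():
        bids = sorted(bids, key=lambda b: (block_map[b].chrom, block_map[b].start))
        if len(bids) == 1:
            rid = bids[0]
        else:
            rid = "+".join(bids)
        regions[rid] = RegionDefinition(
            region_id=rid,
            chrom=block_map[bids[0]].chrom,
            start=min(block_map[b].start for b in bids),
            stop=max(block_map[b].stop for b in bids),
            member_block_ids=bids,
        )
        for b in bids:
            block_to_region[b] = rid

    vtab = variants.copy()
    vtab["region_id"] = vtab["block_id"].map(block_to_region)

    genes: dict[str, list[str]] = {}
    for gene_id, spanned in gene_blocks.items():
        rid = block_to_region[next(iter(spanned))]
        genes.setdefault(rid, []).append(gene_id)
    for rid in genes:
        genes[rid] = sorted(genes[rid])

    return RegionIndex(regions=regions, variants=vtab, genes=genes,
                       rejected_genes=rejected)


def thin_variants(
    region_variants: pd.DataFrame,
    keep_fraction: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Deterministic stride thinning mask over a region's variants.

    Keeps every ceil(1/keep_fraction)-th variant in position order,
    starting at a seed-derived offset (offset 0 when no seed is given).
    eQTL variants of retained genes are re-added downstream when the
    augmented matrix is built, independently of this mask.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    p = len(region_variants)
    mask = np.zeros(p, dtype=bool)
    if p == 0:
        return mask
    if keep_fraction == 1.0:
        mask[:] = True
        return mask
    stride = math.ceil(1.0 / keep_fraction)
    offset = 0
    if seed is not None:
        offset = int(np.random.default_rng(seed).integers(0, stride))
    order = np.argsort(region_variants["pos"].to_numpy(), kind="stable")
    mask[order[offset::stride]] = True
    return mask


def cap_variants(
    region_variants: pd.DataFrame,
    max_variants: int = 20000,
    seed: int | None = None,
) -> np.ndarray:
    """Uniform random subset mask of at most ``max_variants`` variants."""
    if max_variants < 1:
        raise ValueError("max_variants must be >= 1")
    p = len(region_variants)
    mask = np.ones(p, dtype=bool)
    if p <= max_variants:
        return mask
    rng = np.random.default_rng(seed)
    keep = rng.choice(p, size=max_variants, replace=False)
    mask[:] = False
    mask[keep] = True
    logger.info("cap_variants: region of %d capped to %d (seed=%s)",
                p, max_variants, seed)
    return mask


def assemble_region_ld(
    region: RegionDefinition,
    ld_blocks: dict[str, LDBlockMatrix],
    cross_block: np.ndarray | None = None,
) -> np.ndarray:
    """Correlation matrix of a (possibly merged) region.

    Member blocks are laid out block-diagonally in member order;
    cross-block correlations default to zero (blocks are approximately
    independent) unless a full merged matrix ``cross_block`` is supplied.
    """
    if cross_block is not None:
        return cross_block
    mats = [ld_blocks[b].corr for b in region.member_block_ids]
    if len(mats) == 1:
        return mats[0]
    return scipy.linalg.block_diag(*mats)
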