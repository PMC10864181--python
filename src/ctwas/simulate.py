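"""Genome-lite simulator with full ground truth.

Generates, at a scale that runs on a desk machine, data with the
statistical structure the pipeline consumes: LD-blocked genotypes
(common variants, MAF > 0.05), sparse eQTL weight models (1-5 eQTLs per
gene, occasionally spanning two adjacent blocks to exercise region
merging), spike-and-slab causal effects on genes and variants, a
standardized quantitative trait, per-variant GWAS z-scores, and an
in-sample LD panel computed from a subsample of individuals.

Genotypes come from a thresholded latent-Gaussian model: within a block
the latent haplotype values follow an AR(1) process with lag-one
correlation ``ld_decay``, and each haplotype carries the alternate
allele when its latent value falls below the MAF quantile. This yields
Hardy-Weinberg dosages with smoothly decaying within-block LD and
independence across blocks.
"""
from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as ctwas_io
from .types import LDBlockMatrix, RegionDefinition, WeightModel, make_variant_id

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]  # includes ambiguous (A/T, G/C) pairs, as real data would

#: equal-weight normal mixture with component SD ratios 1:2:4:8 has
#: conditional variance (1 + 4 + 16 + 64) / 4 = 21.25 times the base s^2
MIXTURE_SD_RATIOS = np.array([1.0, 2.0, 4.0, 8.0])
MIXTURE_VARIANCE_FACTOR = float(np.mean(MIXTURE_SD_RATIOS**2))


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults give ~30 causal genes (of 300) and ~150 causal variants (of
    30,000) with gene PVE 0.05 and variant PVE 0.2 at a GWAS sample size
    of 5,000.
    """

    n_individuals: int = 5000
    n_blocks: int = 100
    variants_per_block: int = 300
    genes_per_block: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.6  # lag-one latent AR(1) correlation
    eqtls_per_gene: tuple[int, int] = (1, 5)
    span_prob: float = 0.02  # chance a gene's model spans two blocks
    pi_gene: float = 0.1
    pi_variant: float = 0.005
    pve_gene: float = 0.05
    pve_variant: float = 0.2
    effect_dist: str = "normal"  # or "mixture_1248"
    ld_subsample: int | None = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pve_gene + self.pve_variant >= 1:
            raise ValueError("total PVE must be < 1")
        if not (0 <= self.pi_gene <= 1 and 0 <= self.pi_variant <= 1):
            raise ValueError("prior probabilities must be in [0, 1]")
        if self.effect_dist not in ("normal", "mixture_1248"):
            raise ValueError(f"unknown effect_dist {self.effect_dist!r}")


@dataclass
class SimTruth:
    causal_genes: dict[str, float]      # gene_id -> effect (standardized scale)
    causal_variants: dict[str, float]   # variant_id -> effect
    pve_gene_realized: float
    pve_variant_realized: float
    y: np.ndarray                       # standardized phenotype
    sigma_eps: float


@dataclass
class SimBundle:
    config: SimConfig
    genotypes: np.ndarray               # (n, p_total) int8 dosages
    variant_table: pd.DataFrame         # variant_id, chrom, pos, ref, alt, maf
    blocks: list[RegionDefinition]
    weight_models: list[WeightModel]
    gwas: pd.DataFrame                  # harmonizable sumstats table
    ld_blocks: list[LDBlockMatrix]
    truth: SimTruth
    expression: pd.DataFrame | None = field(default=None, repr=False)

    def write(self, out_dir: str | pathlib.Path) -> None:
        """Emit the exact on-disk formats the pipeline reads."""
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ctwas_io.write_gwas_sumstats(
            self.gwas.assign(n_gwas=self.config.n_individuals),
            out / "sumstats.tsv",
        )
        ctwas_io.write_weight_models(
            self.weight_models, out / "weights.tsv", out / "weights_manifest.yaml"
        )
        ctwas_io.write_ld_reference(self.ld_blocks, out / "ld")
        ctwas_io.write_block_definitions(self.blocks, out / "blocks.bed")
        truth = pd.DataFrame(
            [("gene", k, v) for k, v in self.truth.causal_genes.items()]
            + [("variant", k, v) for k, v in self.truth.causal_variants.items()],
            columns=["type", "variable_id", "effect"],
        )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _standardize(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    out = np.zeros_like(g)
    ok = sd > 0
    out[:, ok] = (g[:, ok] - mu[ok]) / sd[ok]
    return out


def _block_positions(config: SimConfig, block: int) -> np.ndarray:
    span = config.variants_per_block * 1000
    return block * span + 1000 * np.arange(config.variants_per_block) + 1


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[RegionDefinition], pd.DataFrame]:
    """Simulate dosages for all blocks; returns (G, blocks, variant_table)."""
    n, m = config.n_individuals, config.variants_per_block
    rho = config.ld_decay
    lo, hi = config.maf_range
    span = m * 1000
    G = np.empty((n, config.n_blocks * m), dtype=np.int8)
    blocks: list[RegionDefinition] = []
    rows = []
    for b in range(config.n_blocks):
        mafs = rng.uniform(lo, hi, size=m)
        latent = np.empty((2 * n, m))
        latent[:, 0] = rng.standard_normal(2 * n)
        noise = rng.standard_normal((2 * n, m - 1)) * np.sqrt(1 - rho**2)
        for j in range(1, m):
            latent[:, j] = rho * latent[:, j - 1] + noise[:, j - 1]
        alleles = latent < norm.ppf(mafs)[None, :]
        G[:, b * m:(b + 1) * m] = (
            alleles[:n].astype(np.int8) + alleles[n:].astype(np.int8)
        )
        pos = _block_positions(config, b)
        pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
        realized = G[:, b * m:(b + 1) * m].mean(axis=0) / 2.0
        for j in range(m):
            ref, alt = pairs[j]
            rows.append(
                ("1", int(pos[j]), ref, alt, float(min(realized[j],
                                                       1 - realized[j])))
            )
        blocks.append(
            RegionDefinition(
                region_id=f"B{b:03d}",
                chrom="1",
                start=b * span + 1,
                stop=(b + 1) * span + 1,
                member_block_ids=[f"B{b:03d}"],
            )
        )
    vt = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])
    vt.insert(
        0,
        "variant_id",
        [make_variant_id(c, p, r, a)
         for c, p, r, a in zip(vt.chrom, vt.pos, vt.ref, vt.alt)],
    )
    return G, blocks, vt


def simulate_weights(
    config: SimConfig,
    variant_table: pd.DataFrame,
    rng: np.random.Generator,
) -> list[WeightModel]:
    """Sparse standardized-scale eQTL weight models, 1-5 eQTLs per gene."""
    m = config.variants_per_block
    lo, hi = config.eqtls_per_gene
    models = []
    for b in range(config.n_blocks):
        for g in range(config.genes_per_block):
            k = int(rng.integers(lo, hi + 1))
            spanning = (
                config.span_prob > 0
                and b + 1 < config.n_blocks
                and k >= 2
                and rng.random() < config.span_prob
            )
            if spanning:
                k2 = int(rng.integers(1, k))
                idx = np.concatenate([
                    b * m + rng.choice(m, size=k - k2, replace=False),
                    (b + 1) * m + rng.choice(m, size=k2, replace=False),
                ])
            else:
                idx = b * m + rng.choice(m, size=k, replace=False)
            idx = np.sort(idx)
            w = rng.standard_normal(k)
            w[w == 0] = 1e-3
            variants = variant_table.iloc[idx][
                ["variant_id", "chrom", "pos", "ref", "alt"]
            ].reset_index(drop=True)
            models.append(
                WeightModel(
                    gene_id=f"G{b:03d}_{g}",
                    chrom="1",
                    tss_pos=int(variants["pos"].min()),
                    variants=variants,
                    weights=w,
                    scale="standardized",
                )
            )
    return models


def _draw_effects(
    n_causal: int, var_per_effect: float, dist: str, rng: np.random.Generator
) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal(n_causal) * np.sqrt(var_per_effect)
    # equal mixture of N(0, (w s)^2), w in 1:2:4:8, scaled to match the
    # target per-effect variance
    s = np.sqrt(var_per_effect / MIXTURE_VARIANCE_FACTOR)
    comp = MIXTURE_SD_RATIOS[rng.integers(0, 4, size=n_causal)]
    return rng.standard_normal(n_causal) * comp * s


def imputed_expression(
    G: np.ndarray, models: list[WeightModel], variant_table: pd.DataFrame
) -> pd.DataFrame:
    """Standardized cis-genetic expression of every gene, individuals x genes."""
    row_of = {v: i for i, v in enumerate(variant_table["variant_id"])}
    out = {}
    for mod in models:
        idx = np.array([row_of[v] for v in mod.variant_ids])
        gs = _standardize(G[:, idx])
        e = gs @ mod.weights
        sd = e.std()
        out[mod.gene_id] = (e - e.mean()) / sd if sd > 0 else e
    return pd.DataFrame(out)


def simulate_trait(
    G: np.ndarray,
    models: list[WeightModel],
    variant_table: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    expression: pd.DataFrame | None = None,
) -> SimTruth:
    """Draw causal variables and effects, then the phenotype.

    Causal indicators are Bernoulli(pi_k); per-effect variances are set
    by inverting PVE_k = pi_k |M_k| sigma_beta^2 so the expected group
    PVE matches the target; the residual completes unit total variance.
    """
    if expression is None:
        expression = imputed_expression(G, models, variant_table)
    n = G.shape[0]
    gene_ids = list(expression.columns)
    p_var = G.shape[1]

    def draw_mask(p: float, size: int) -> np.ndarray:
        mask = rng.random(size) < p
        if p > 0 and not mask.any():
            mask = rng.random(size) < p  # one resample, then accept
            if not mask.any():
                logger.warning("no causal variables drawn at pi=%g", p)
        return mask

    # a group with zero target PVE carries no causal variables
    gene_mask = (
        draw_mask(config.pi_gene, len(gene_ids)) if config.pve_gene > 0
        else np.zeros(len(gene_ids), dtype=bool)
    )
    var_mask = (
        draw_mask(config.pi_variant, p_var) if config.pve_variant > 0
        else np.zeros(p_var, dtype=bool)
    )

    var_g = (
        config.pve_gene / max(config.pi_gene * len(gene_ids), 1e-300)
        if config.pve_gene > 0 else 0.0
    )
    var_v = (
        config.pve_variant / max(config.pi_variant * p_var, 1e-300)
        if config.pve_variant > 0 else 0.0
    )
    beta = _draw_effects(int(gene_mask.sum()), var_g, config.effect_dist, rng)
    theta = _draw_effects(int(var_mask.sum()), var_v, "normal", rng)

    y_gene = np.zeros(n)
    if gene_mask.any() and config.pve_gene > 0:
        y_gene = expression.to_numpy()[:, gene_mask] @ beta
    y_var = np.zeros(n)
    if var_mask.any() and config.pve_variant > 0:
        y_var = _standardize(G[:, var_mask]) @ theta
    sigma_eps = float(np.sqrt(max(1.0 - config.pve_gene - config.pve_variant,
                                  1e-12)))
    y = y_gene + y_var + rng.standard_normal(n) * sigma_eps
    var_y = y.var()
    truth = SimTruth(
        causal_genes={
            gid: float(b)
            for gid, b in zip(np.array(gene_ids)[gene_mask], beta)
        },
        causal_variants={
            vid: float(t)
            for vid, t in zip(
                variant_table["variant_id"].to_numpy()[var_mask], theta)
        },
        pve_gene_realized=float(y_gene.var() / var_y),
        pve_variant_realized=float(y_var.var() / var_y),
        y=(y - y.mean()) / np.sqrt(var_y),
        sigma_eps=sigma_eps,
    )
    return truth


def compute_sumstats(
    G: np.ndarray,
    y: np.ndarray,
    variant_table: pd.DataFrame,
    blocks: list[RegionDefinition],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[LDBlockMatrix]]:
    """Per-variant z-scores and in-sample LD.

    z_m = sqrt(n) * cor(G_m, y); the LD panel uses ``ld_subsample``
    randomly chosen individuals (all of them when None). Monomorphic
    variants get z = 0 and are flagged.
    """
    n, p = G.shape
    m = config.variants_per_block
    ys = (y - y.mean()) / y.std()
    if config.ld_subsample is None or config.ld_subsample >= n:
        sub = np.arange(n)
    else:
        sub = np.sort(rng.choice(n, size=config.ld_subsample, replace=False))
    z = np.empty(p)
    mono = np.zeros(p, dtype=bool)
    ld_blocks = []
    for b, blk in enumerate(blocks):
        sl = slice(b * m, (b + 1) * m)
        gs = _standardize(G[:, sl])
        sd = G[:, sl].astype(float).std(axis=0)
        z[sl] = gs.T @ ys / np.sqrt(n)
        mono[sl] = sd == 0
        z[sl][sd == 0] = 0.0
        gsub = _standardize(G[sub, sl])
        corr = gsub.T @ gsub / len(sub)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        ld_blocks.append(
            LDBlockMatrix(
                block_id=blk.region_id,
                variants=variant_table.iloc[sl].reset_index(drop=True),
                corr=corr,
            )
        )
    if mono.any():
        logger.warning("%d monomorphic variants flagged with z=0",
                       int(mono.sum()))
    gwas = variant_table[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    gwas["z"] = z
    gwas["n_gwas"] = n
    return gwas, ld_blocks


def simulate(config: SimConfig) -> SimBundle:
    """Full generative run: genotypes -> weights -> trait -> summary data."""
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_w, rng_trait, rng_ld = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    G, blocks, vt = simulate_genotypes(config, rng_geno)
    models = simulate_weights(config, vt, rng_w)
    expression = imputed_expression(G, models, vt)
    truth = simulate_trait(G, models, vt, config, rng_trait,
                           expression=expression)
    gwas, ld_blocks = compute_sumstats(G, truth.y, vt, blocks, config, rng_ld)
    return SimBundle(
        config=config,
        genotypes=G,
        variant_table=vt,
        blocks=blocks,
        weight_models=models,
        gwas=gwas,
        ld_blocks=ld_blocks,
        truth=truth,
        expression=expression,
    )
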