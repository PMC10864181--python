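"""The genome-lite generator: genotypes, weights, traits, summary data."""
import numpy as np
import pytest

from ctwas.augment import gene_z
from ctwas.simulate import (
    MIXTURE_SD_RATIOS,
    MIXTURE_VARIANCE_FACTOR,
    SimConfig,
    _draw_effects,
    imputed_expression,
    simulate,
    simulate_genotypes,
)


def _tiny(**kw):
    defaults = dict(
        n_individuals=400, n_blocks=4, variants_per_block=40,
        genes_per_block=2, ld_subsample=None, seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_reproduces_everything(small_config):
    b1 = simulate(small_config)
    b2 = simulate(small_config)
    np.testing.assert_array_equal(b1.genotypes, b2.genotypes)
    np.testing.assert_array_equal(b1.gwas["z"], b2.gwas["z"])
    assert b1.truth.causal_genes == b2.truth.causal_genes


def test_realized_mafs_within_bounds(small_bundle, small_config):
    lo, hi = small_config.maf_range
    maf = small_bundle.variant_table["maf"]
    assert (maf >= lo - 0.05).all() and (maf <= 0.5).all()


def test_low_ld_decay_gives_near_independent_variants():
    cfg = _tiny(ld_decay=0.01, n_individuals=2000)
    rng = np.random.default_rng(0)
    G, _, _ = simulate_genotypes(cfg, rng)
    g = G[:, :40].astype(float)
    g = (g - g.mean(0)) / g.std(0)
    corr = g.T @ g / len(g)
    off = np.abs(corr[np.triu_indices(40, 1)])
    assert off.mean() < 0.05


def test_eqtl_counts_and_weights(small_bundle):
    for m in small_bundle.weight_models:
        assert 1 <= len(m.weights) <= 5
        assert np.all(np.isfinite(m.weights))
        assert np.all(m.weights != 0)


def test_spanning_gene_present_and_merged(small_bundle):
    """With a nonzero spanning probability some gene's model crosses two
    adjacent blocks, exercising the region-merge path downstream."""
    block_of = {}
    for blk in small_bundle.ld_blocks:
        for v in blk.variants["variant_id"]:
            block_of[v] = blk.block_id
    spans = [
        len({block_of[v] for v in m.variant_ids}) > 1
        for m in small_bundle.weight_models
    ]
    assert any(spans)


def test_null_trait_z_standard_normal():
    # near-independent variants so the mean of z has small standard error
    cfg = _tiny(pve_gene=0.0, pve_variant=0.0, n_individuals=1500,
                n_blocks=6, ld_decay=0.05)
    bundle = simulate(cfg)
    z = bundle.gwas["z"].to_numpy()
    assert abs(z.mean()) < 3.5 / np.sqrt(len(z))
    assert 0.8 < z.var() < 1.25
    assert not bundle.truth.causal_genes and not bundle.truth.causal_variants


def test_planted_strong_variant_yields_large_z():
    cfg = _tiny(pi_gene=0.0, pve_gene=0.0, pi_variant=0.02,
                pve_variant=0.5, n_individuals=2000)
    bundle = simulate(cfg)
    z = bundle.gwas.set_index("variant_id")["z"]
    big = [abs(z[v]) for v in bundle.truth.causal_variants]
    assert max(big) > 6


def test_realized_pve_tracks_targets():
    fractions = []
    for seed in range(8):
        cfg = _tiny(seed=seed, n_individuals=1200, pve_gene=0.1,
                    pve_variant=0.2, pi_gene=0.3, pi_variant=0.02)
        bundle = simulate(cfg)
        fractions.append(
            (bundle.truth.pve_gene_realized, bundle.truth.pve_variant_realized)
        )
    g, v = np.mean(fractions, axis=0)
    assert g == pytest.approx(0.1, abs=0.05)
    assert v == pytest.approx(0.2, abs=0.07)


def test_causal_counts_match_priors():
    counts = []
    for seed in range(6):
        cfg = _tiny(seed=seed, pi_gene=0.25, pi_variant=0.02)
        counts.append(
            (len(simulate(cfg).truth.causal_genes))
        )
    # 8 genes at pi=0.25 -> mean 2; allow binomial spread across 6 draws
    assert 0.5 < np.mean(counts) < 4.0


def test_mixture_effect_distribution_variance_and_tails():
    rng = np.random.default_rng(0)
    target = 2.0
    draws = _draw_effects(60000, target, "mixture_1248", rng)
    assert draws.var() == pytest.approx(target, rel=0.05)
    # component SDs in ratio 1:2:4:8 -> strong excess kurtosis vs normal
    k = np.mean(draws**4) / draws.var() ** 2
    assert k > 5.0
    assert MIXTURE_VARIANCE_FACTOR == pytest.approx(
        np.mean(MIXTURE_SD_RATIOS**2)
    )


def test_mixture_trait_end_to_end():
    cfg = _tiny(effect_dist="mixture_1248", pi_gene=0.3, pve_gene=0.15)
    bundle = simulate(cfg)
    assert bundle.truth.causal_genes


def test_gene_z_matches_individual_level_regression(small_bundle):
    """With in-sample LD from all individuals, the summary-statistic gene
    z-score equals the z-score of regressing the trait on the gene's
    standardized imputed expression."""
    bundle = small_bundle
    n = bundle.config.n_individuals
    y = bundle.truth.y
    ys = (y - y.mean()) / y.std()
    expr = imputed_expression(bundle.genotypes, bundle.weight_models,
                              bundle.variant_table)
    z_by_id = bundle.gwas.set_index("variant_id")["z"]
    corr_by_block = {b.block_id: b for b in bundle.ld_blocks}
    block_of = {}
    index_of = {}
    for blk in bundle.ld_blocks:
        for i, v in enumerate(blk.variants["variant_id"]):
            block_of[v] = blk.block_id
            index_of[v] = i
    checked = 0
    for m in bundle.weight_models:
        blocks = {block_of[v] for v in m.variant_ids}
        if len(blocks) > 1:
            continue  # LD matrix spans one block only
        blk = corr_by_block[blocks.pop()]
        idx = [index_of[v] for v in m.variant_ids]
        R_v = blk.corr[np.ix_(idx, idx)]
        z_v = z_by_id[m.variant_ids].to_numpy()
        z_summary = gene_z(m.weights, z_v, R_v)
        e = expr[m.gene_id].to_numpy()
        z_individual = np.sqrt(n) * float(e @ ys) / n
        assert z_summary == pytest.approx(z_individual, abs=1e-6)
        checked += 1
    assert checked > 5


def test_bundle_round_trips_through_files(tmp_path, small_bundle):
    from ctwas import io as ctwas_io

    small_bundle.write(tmp_path)
    gwas = ctwas_io.read_gwas_sumstats(tmp_path / "sumstats.tsv")
    assert len(gwas) == len(small_bundle.gwas)
    models = ctwas_io.read_weight_models(
        tmp_path / "weights.tsv", tmp_path / "weights_manifest.yaml"
    )
    assert len(models) == len(small_bundle.weight_models)
    ld = ctwas_io.read_ld_reference(tmp_path / "ld")
    assert len(ld) == len(small_bundle.ld_blocks)
    np.testing.assert_allclose(
        ld[0].corr, small_bundle.ld_blocks[0].corr, atol=1e-12
    )
    blocks = ctwas_io.read_block_definitions(tmp_path / "blocks.bed")
    assert [b.region_id for b in blocks] == [
        b.region_id for b in small_bundle.blocks
    ]
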