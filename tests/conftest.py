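import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctwas.simulate import SimConfig, simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")
from ctwas.types import LDBlockMatrix, WeightModel, make_variant_id


def variant_frame(specs):
    """Build a variant table from (chrom, pos, ref, alt[, maf]) tuples."""
    rows = []
    for s in specs:
        chrom, pos, ref, alt = s[:4]
        row = {
            "variant_id": make_variant_id(chrom, pos, ref, alt),
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
        if len(s) > 4:
            row["maf"] = s[4]
        rows.append(row)
    return pd.DataFrame(rows)


def make_block(block_id, specs, corr=None):
    vt = variant_frame(specs)
    if "maf" not in vt:
        vt["maf"] = 0.3
    if corr is None:
        corr = np.eye(len(vt))
    return LDBlockMatrix(block_id=block_id, variants=vt, corr=np.asarray(corr, float))


def make_model(gene_id, specs, weights, chrom="1", scale="standardized"):
    vt = variant_frame(specs)
    return WeightModel(
        gene_id=gene_id,
        chrom=chrom,
        tss_pos=int(vt["pos"].min()),
        variants=vt,
        weights=np.asarray(weights, float),
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_config():
    """Desk-toy study conditions: enough structure to exercise every
    pipeline stage in a couple of seconds."""
    return SimConfig(
        n_individuals=800,
        n_blocks=6,
        variants_per_block=60,
        genes_per_block=2,
        pi_gene=0.25,
        pi_variant=0.01,
        pve_gene=0.1,
        pve_variant=0.15,
        ld_subsample=None,
        span_prob=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate(small_config)
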