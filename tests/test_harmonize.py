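"""Allele classification and harmonization of z-scores and weights."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctwas.augment import gene_z
from ctwas.harmonize import (
    ModelRejected,
    classify_allele_pair,
    harmonize_weights,
    harmonize_z,
    standardize_weights,
)

from conftest import make_block, make_model, variant_frame

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@pytest.mark.parametrize(
    "ref, other, expected",
    [
        (("G", "A"), ("G", "A"), "match"),
        (("G", "A"), ("C", "T"), "switched"),
        (("A", "T"), ("T", "A"), "ambiguous"),
        (("G", "A"), ("A", "G"), "flipped"),
        (("C", "G"), ("C", "G"), "ambiguous"),
        (("A", "T"), ("A", "T"), "ambiguous"),
        (("G", "C"), ("G", "C"), "ambiguous"),
        (("G", "A"), ("T", "C"), "flipped"),  # flipped on the other strand
        (("G", "A"), ("G", "C"), "incompatible"),
        (("A", "C"), ("A", "G"), "incompatible"),
        (("A", "C"), ("G", "T"), "flipped"),  # reversed complement
    ],
)
def test_classify_allele_pair_truth_table(ref, other, expected):
    assert classify_allele_pair(ref, other) == expected


def test_classify_rejects_invalid_alleles():
    with pytest.raises(ValueError):
        classify_allele_pair(("N", "A"), ("G", "A"))
    with pytest.raises(ValueError):
        classify_allele_pair(("A", "A"), ("A", "A"))


_pairs = st.sampled_from(
    [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
)


@given(pair=_pairs)
def test_classify_identity_is_match_or_ambiguous(pair):
    """A pair compared with itself is a match, unless the alleles are a
    complementary pair, in which case flip and switch are indistinguishable
    even for identical records."""
    result = classify_allele_pair(pair, pair)
    if pair[1] == COMP[pair[0]]:
        assert result == "ambiguous"
    else:
        assert result == "match"


@given(ref=_pairs, other=_pairs)
@settings(max_examples=200)
def test_classify_invariant_under_double_complement(ref, other):
    """Complementing both pairs (renaming both strands) never changes the
    classification of non-ambiguous pairs."""
    base = classify_allele_pair(ref, other)
    comp = classify_allele_pair(
        (COMP[ref[0]], COMP[ref[1]]), (COMP[other[0]], COMP[other[1]])
    )
    if base != "ambiguous":
        assert comp == base


def _gwas(specs, z):
    df = variant_frame(specs)
    df["z"] = z
    df["n_gwas"] = 1000
    return df


def test_harmonize_z_flip_switch_and_drop():
    ld = [make_block("B0", [("1", 100, "G", "A"), ("1", 200, "C", "A"),
                            ("1", 300, "T", "G")])]
    gwas = _gwas(
        [("1", 100, "A", "G"),   # flipped -> sign reversed
         ("1", 200, "G", "T"),   # switched -> unchanged
         ("1", 300, "T", "G"),   # match
         ("1", 400, "A", "C"),   # absent from LD -> dropped
         ("1", 300, "A", "G")],  # incompatible -> dropped
        z=[2.5, 1.0, -0.5, 3.0, 1.0],
    )
    out = harmonize_z(gwas, ld)
    assert len(out) == 3
    assert out.loc[out.pos == 100, "z"].item() == -2.5
    assert out.loc[out.pos == 200, "z"].item() == 1.0
    assert out.loc[out.pos == 300, "z"].item() == -0.5
    # output adopts the reference allele orientation
    assert out.loc[out.pos == 100, "alt"].item() == "A"


def test_harmonize_z_is_idempotent():
    ld = [make_block("B0", [("1", 100, "G", "A"), ("1", 200, "A", "T"),
                            ("1", 300, "C", "A")])]
    gwas = _gwas(
        [("1", 100, "A", "G"), ("1", 200, "T", "A"), ("1", 300, "G", "T")],
        z=[1.5, -2.0, 0.7],
    )
    once = harmonize_z(gwas, ld)
    twice = harmonize_z(once, ld)
    pd.testing.assert_frame_equal(once, twice)


def test_harmonize_z_ambiguous_passthrough_and_sign_imputation():
    """Perfectly correlated unambiguous partner with opposite-sign z flips
    the ambiguous variant's sign; magnitudes never change."""
    corr = np.array([[1.0, 1.0], [1.0, 1.0]])
    ld = [make_block("B0", [("1", 100, "A", "T"), ("1", 200, "G", "A")], corr)]
    gwas = _gwas([("1", 100, "A", "T"), ("1", 200, "G", "A")], z=[-3.0, 3.0])
    out_off = harmonize_z(gwas, ld, resolve_ambiguous=False)
    assert out_off.loc[out_off.pos == 100, "z"].item() == -3.0
    out_on = harmonize_z(gwas, ld, resolve_ambiguous=True)
    assert out_on.loc[out_on.pos == 100, "z"].item() == 3.0
    assert out_on.loc[out_on.pos == 200, "z"].item() == 3.0


def test_harmonize_z_no_ambiguous_block_untouched():
    ld = [make_block("B0", [("1", 100, "G", "A"), ("1", 200, "C", "A")])]
    gwas = _gwas([("1", 100, "G", "A"), ("1", 200, "C", "A")], z=[1.0, 2.0])
    out = harmonize_z(gwas, ld, resolve_ambiguous=True)
    assert list(out["z"]) == [1.0, 2.0]


def test_harmonize_weights_flip_negated():
    ld = [make_block("B0", [("1", 100, "G", "A"), ("1", 200, "C", "A")])]
    model = make_model(
        "g1", [("1", 100, "A", "G"), ("1", 200, "C", "A")], [0.4, 0.2]
    )
    out = harmonize_weights(model, ld)
    assert out.weights.tolist() == [-0.4, 0.2]


def test_harmonize_weights_single_ambiguous_retained_unchanged():
    ld = [make_block("B0", [("1", 100, "A", "T")])]
    model = make_model("g1", [("1", 100, "T", "A")], [0.7])
    out = harmonize_weights(model, ld)
    assert out.weights.tolist() == [0.7]


def test_harmonize_weights_multiple_ambiguous_no_unambiguous_rejected():
    ld = [make_block("B0", [("1", 100, "A", "T"), ("1", 200, "G", "C")])]
    model = make_model(
        "g1", [("1", 100, "A", "T"), ("1", 200, "G", "C")], [0.5, 0.5]
    )
    with pytest.raises(ModelRejected):
        harmonize_weights(model, ld)


def test_harmonize_weights_ambiguous_sign_resolution():
    """Ambiguous weight sign reversed iff model-LD and reference-LD
    correlation sums disagree; zero reference sum zeroes the weight."""
    corr = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
    ld = [make_block(
        "B0",
        [("1", 100, "A", "T"), ("1", 200, "G", "A"), ("1", 300, "A", "T")],
        corr,
    )]
    model = make_model(
        "g1",
        [("1", 100, "A", "T"), ("1", 200, "G", "A"), ("1", 300, "A", "T")],
        [0.5, 0.2, 0.3],
    )
    cov = pd.DataFrame(
        {
            "GENE": ["g1", "g1"],
            "VAR1": ["1:100:A:T", "1:300:A:T"],
            "VAR2": ["1:200:G:A", "1:200:G:A"],
            "COV": [-0.4, 0.2],  # disagrees / ref sum is 0
        }
    )
    out = harmonize_weights(model, ld, model_ld_cov=cov)
    w = dict(zip(out.variants["pos"], out.weights))
    assert w[100] == -0.5   # sign disagreement -> reversed
    assert w[300] == 0.0    # zero reference correlation sum -> zeroed
    assert w[200] == 0.2


def test_standardize_weights_scales_by_genotype_sd():
    model = make_model(
        "g1", [("1", 100, "G", "A"), ("1", 200, "C", "A"), ("1", 300, "T", "C")],
        [0.5, 0.5, 0.9], scale="per_allele",
    )
    out = standardize_weights(model, np.array([1.0, 0.5, 0.0]))
    assert out.scale == "standardized"
    assert out.weights.tolist() == [0.5, 0.25]  # zero-variance variant dropped
    assert len(out.variants) == 2


def test_weight_and_allele_flip_round_trip_preserves_gene_z():
    """Reversing a variant's allele order while negating its weight leaves
    the harmonized gene z-score unchanged."""
    corr = np.array([[1.0, 0.3], [0.3, 1.0]])
    ld = [make_block("B0", [("1", 100, "G", "A"), ("1", 200, "C", "A")], corr)]
    z_v = np.array([2.0, -1.0])
    base = make_model("g1", [("1", 100, "G", "A"), ("1", 200, "C", "A")],
                      [0.4, 0.6])
    flipped = make_model("g1", [("1", 100, "A", "G"), ("1", 200, "C", "A")],
                         [-0.4, 0.6])
    h1 = harmonize_weights(base, ld)
    h2 = harmonize_weights(flipped, ld)
    assert gene_z(h1.weights, z_v, corr) == pytest.approx(
        gene_z(h2.weights, z_v, corr), abs=1e-12
    )
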