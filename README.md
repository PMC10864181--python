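# ctwas — causal TWAS from GWAS summary statistics

Transcriptome-wide association studies (TWAS) test whether genetically
imputed gene expression associates with a trait, but a significant TWAS
gene is often not causal: its imputed expression can be correlated —
through linkage disequilibrium (LD) or shared eQTLs — with a nearby
causal variant or with another gene's expression. This package
implements causal TWAS (cTWAS): a joint Bayesian fine-mapping of
**imputed genes and genetic variants together**, so that each gene must
compete against every local variant (and neighboring gene) for the
association signal it claims.

It is intended for statistical geneticists working with GWAS variant
summary statistics, eQTL expression prediction models (FUSION- or
PredictDB-style sparse weights), and a block-wise LD reference panel.

## Model

Phenotype `y` (standardized) is regressed jointly on standardized
imputed expressions and variant genotypes,

    y = Σ_j β_j X̃_j + Σ_m θ_m G_m + ε,       ε ~ N(0, σ²)

with a group-level spike-and-slab prior on every effect: for variable
`j` in group `k` (gene or variant),

    γ_j ~ Bernoulli(π_k),   β_j | γ_j=1 ~ N(0, σ²_k),   β_j | γ_j=0 = 0.

Working from summary statistics, variant z-scores `ẑ` and their
correlation matrix `R` follow `ẑ | z, R ~ N(Rz, R)`; each gene is added
as a derived variable with z-score `wᵀẑ_v / √(wᵀR_v w)` from its eQTL
weights `w`, and the correlation matrix is extended to genes
accordingly. Inference proceeds in two steps:

1. **Empirical-Bayes prior estimation.** The four parameters
   (π_gene, π_variant, σ²_gene, σ²_variant) are estimated by EM.
   The E-step fine-maps each LD region under a single causal effect
   (L = 1), yielding inclusion probabilities α_j and posterior second
   moments τ²_j; the M-step sets π_k to the group mean of α and σ²_k to
   the α-weighted mean of τ². Variants are thinned to a 10% stride for
   this step.
2. **Fine-mapping.** Each region is fit with a sum of L = 5 single
   effects under the estimated priors (prior inclusion π_k per
   variable, per-effect null weight 1 − Σπ_j). Regions whose top gene
   PIP exceeds 0.8 are refit with the full variant set (capped at
   20,000 variants). Credible sets are reported at 95% coverage with
   purity (min |r|) > 0.5.

The estimated priors also yield the variance explained per group,
`PVE_k = σ²_k · π_k · |M_k| / n`, and hence the fraction of heritability
attributable to expression.

## Worked example

```python
from ctwas import CTWAS, SimConfig, simulate

config = SimConfig(seed=42)   # 5,000 individuals, 100 LD blocks x 300 variants x 3 genes
bundle = simulate(config)     # genotypes, weights, z-scores, LD, ground truth
results = CTWAS.from_bundle(bundle).fit(seed=1)
print(results.summary())
```

```
cTWAS results
============================================================
variables analyzed: 285 genes, 5855 variants (94 regions, 8 rescued)

Group prior estimates (z-score scale)
  pi_gene        7.7640e-02
  pi_variant     8.0729e-03
  sigma2_gene    12.6801
  sigma2_variant 5.9345
  enrichment (pi_gene/pi_variant): 9.62

Variance explained
  PVE genes     0.0561
  PVE variants  0.2875
  total         0.3436
  attributable to expression: 16.3%

genes with PIP > 0.8: 7
  G069_2               PIP=0.999 z=-7.56  region=B069
  ...
```

This simulation planted causal genes at prior 0.1 with total gene PVE
0.05 and causal variants at prior 0.005 with variant PVE 0.2. The
summary shows the recovered priors (enrichment 9.6, i.e. a gene is ~10x
more likely causal than a variant a priori; the simulated value is 20),
the PVE split (estimated 0.056 gene / 0.29 variant against realized
values near 0.05 / 0.2), and seven genes above the PIP 0.8 threshold —
all seven of which are truly causal in this replicate
(`results.significant_genes()` against `bundle.truth.causal_genes`).

The same run is available from the shell:

```bash
ctwas simulate --seed 42 --out-dir data/
ctwas run --sumstats data/sumstats.tsv --weights data/weights.tsv \
      --weights-manifest data/weights_manifest.yaml \
      --ld-dir data/ld --blocks data/blocks.bed --seed 1 --out-dir out/
ctwas evaluate --results out/results.tsv --truth data/truth.tsv
```

File formats (tab-delimited sumstats with CHR/POS/A1/A2/Z-or-BETA+SE/N,
per-gene weight tables, NPZ LD matrices with a variant sidecar, BED-like
block definitions) are documented in `ctwas/io.py`; the simulator emits
exactly these formats, so the whole pipeline runs with zero downloads.

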