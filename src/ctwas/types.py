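"""Core domain types shared across the package.

Variant-level tables (GWAS summary statistics, LD sidecars) are plain
pandas DataFrames with a fixed column contract; the richer objects that
carry linear-algebra state are dataclasses defined here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Column contract for variant tables (GWAS sumstats after read/harmonize,
#: LD sidecars).  ``variant_id`` is "chrom:pos:ref:alt".
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def validate_allele(a: str) -> str:
    a = str(a).upper()
    if a not in VALID_ALLELES:
        raise ValueError(f"invalid allele {a!r}: must be one of A, C, G, T")
    return a


@dataclass
class WeightModel:
    """Sparse eQTL weights predicting one gene's cis expression.

    ``weights`` live on the standardized-genotype scale after
    harmonization; per-allele (PredictDB-style) weights are converted by
    :func:`ctwas.harmonize.standardize_weights`.
    """

    gene_id: str
    chrom: str
    tss_pos: int
    variants: pd.DataFrame  # VARIANT_COLUMNS
    weights: np.ndarray
    scale: str = "standardized"  # or "per_allele"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variants) != len(self.weights):
            raise ValueError("variants and weights length mismatch")
        if len(self.weights) == 0:
            raise ValueError("weight model must contain at least one variant")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.scale not in ("standardized", "per_allele"):
            raise ValueError(f"unknown weight scale {self.scale!r}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])


@dataclass
class LDBlockMatrix:
    """Pairwise genotype correlation matrix for one LD block.

    ``variants`` carries VARIANT_COLUMNS plus ``maf``; row order matches
    ``corr``.
    """

    block_id: str
    variants: pd.DataFrame
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        p = len(self.variants)
        if self.corr.shape != (p, p):
            raise ValueError("corr shape does not match variant count")
        if p:
            if not np.allclose(np.diag(self.corr), 1.0, atol=1e-6):
                raise ValueError("LD matrix must have unit diagonal")
            if not np.allclose(self.corr, self.corr.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])


@dataclass
class RegionDefinition:
    """A genomic analysis region: one LD block or a union of merged blocks."""

    region_id: str
    chrom: str
    start: int  # half-open [start, stop), 1-based start
    stop: int
    member_block_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError("region start must be < stop")


@dataclass
class AugmentedRegion:
    """Joint z-vector and correlation matrix over genes + variants in a region.

    Variables are ordered genes first then variants; ``group_labels`` holds
    "gene"/"variant" per variable.
    """

    region_id: str
    variable_ids: list[str]
    group_labels: np.ndarray  # dtype=object, values "gene"/"variant"
    z: np.ndarray
    corr: np.ndarray
    n_gwas: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        p = len(self.variable_ids)
        if not (self.z.shape == (p,) and self.corr.shape == (p, p)):
            raise ValueError("inconsistent AugmentedRegion dimensions")

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    @property
    def is_gene(self) -> np.ndarray:
        return self.group_labels == "gene"


@dataclass
class SERPrior:
    """Prior for a single-effect regression: per-variable inclusion
    weights ``pi``, per-variable slab variances ``sigma2`` (z-score scale),
    and the probability ``null_weight`` that the effect is absent."""

    pi: np.ndarray
    sigma2: np.ndarray
    null_weight: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.sigma2 = np.broadcast_to(
            np.asarray(self.sigma2, dtype=float), self.pi.shape
        ).copy()
        if np.any(self.pi < 0) or np.any(self.sigma2 < 0):
            raise ValueError("pi and sigma2 must be nonnegative")
        total = self.pi.sum() + self.null_weight
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"pi + null_weight must sum to 1 (got {total})")


@dataclass
class SERPosterior:
    """Posterior of a single-effect regression."""

    alpha: np.ndarray        # posterior inclusion per variable
    alpha_null: float        # posterior probability of no effect
    mu1: np.ndarray          # posterior mean given inclusion
    s1_sq: np.ndarray        # posterior variance given inclusion
    lbf: np.ndarray          # per-variable log Bayes factors
    lbf_total: float         # log BF of the whole single-effect model


@dataclass
class CredibleSet:
    members: list[str]
    coverage: float
    purity: float
    cs_id: str = ""


@dataclass
class SusieFit:
    """Sum-of-single-effects fit over one region."""

    region_id: str
    variable_ids: list[str]
    group_labels: np.ndarray
    L: int
    alpha: np.ndarray        # (L, p) per-effect inclusion
    alpha_null: np.ndarray   # (L,) per-effect null mass
    mu1: np.ndarray          # (L, p)
    s1_sq: np.ndarray        # (L, p)
    lbf_total: np.ndarray    # (L,)
    converged: bool
    n_iter: int
    elbo: np.ndarray         # objective trajectory
    credible_sets: list[CredibleSet] = field(default_factory=list)

    @property
    def pip(self) -> np.ndarray:
        """Per-variable PIP: 1 - prod_l (1 - alpha_lj)."""
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)


@dataclass
class GroupPriorEstimate:
    """Spike-and-slab group prior parameters (z-score scale)."""

    pi_gene: float
    pi_variant: float
    sigma2_gene: float
    sigma2_variant: float
    group_sizes: dict = field(default_factory=dict)
    trajectory: pd.DataFrame | None = None

    @property
    def enrichment(self) -> float:
        """Prior odds ratio pi_gene / pi_variant of genes vs variants."""
        if self.pi_variant == 0:
            return np.inf if self.pi_gene > 0 else np.nan
        return self.pi_gene / self.pi_variant

    def pi_for(self, group: str) -> float:
        return self.pi_gene if group == "gene" else self.pi_variant

    def sigma2_for(self, group: str) -> float:
        return self.sigma2_gene if group == "gene" else self.sigma2_variant

    def to_dict(self) -> dict:
        return {
            "pi_gene": float(self.pi_gene),
            "pi_variant": float(self.pi_variant),
            "sigma2_gene": float(self.sigma2_gene),
            "sigma2_variant": float(self.sigma2_variant),
            "enrichment": float(self.enrichment),
            "group_sizes": {k: int(v) for k, v in self.group_sizes.items()},
        }


@dataclass
class PveReport:
    """Per-group proportion of phenotypic variance explained."""

    pve_gene: float
    pve_variant: float
    n_gwas: int

    @property
    def total(self) -> float:
        return self.pve_gene + self.pve_variant

    @property
    def attributable_to_expression(self) -> float:
        """Fraction of explained variance mediated by gene expression."""
        if self.total == 0:
            return float("nan")
        return self.pve_gene / self.total

    def to_dict(self) -> dict:
        return {
            "pve_gene": float(self.pve_gene),
            "pve_variant": float(self.pve_variant),
            "total": float(self.total),
            "attributable_to_expression": float(self.attributable_to_expression),
            "n_gwas": int(self.n_gwas),
        }
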