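"""Model/Results interface over the pipeline.

``CTWAS`` holds harmonizable inputs (GWAS summary statistics, eQTL
weight models, an LD reference, LD block definitions); ``fit()`` runs
prior estimation and two-pass fine-mapping and returns a
``CTWASResults`` carrying the prior estimates, per-variable PIPs,
credible sets, PVE decomposition and a text ``summary()``.
"""
from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from . import io as ctwas_io
from .pipeline import PipelineConfig, RunArtifacts, run_ctwas
from .types import LDBlockMatrix, RegionDefinition, WeightModel


class CTWAS:
    """Joint gene + variant fine-mapping model on GWAS summary statistics.

    Parameters
    ----------
    gwas
        Variant table (variant_id, chrom, pos, ref, alt, z, n_gwas).
    weight_models
        Per-gene sparse eQTL weight models.
    ld_blocks
        LD reference, one correlation matrix per approximately
        independent block.
    blocks
        Block definitions tiling the genome.
    model_ld_cov
        Optional pairwise weight-variant covariances from the expression
        model's own LD panel (used to resolve strand-ambiguous weights).

    Examples
    --------
    >>> from ctwas.simulate import SimConfig, simulate
    >>> bundle = simulate(SimConfig(n_blocks=4, seed=1))
    >>> model = CTWAS.from_bundle(bundle)
    >>> res = model.fit(seed=1)
    >>> res.significant_genes()  # genes with PIP > 0.8  # doctest: +SKIP
    """

    def __init__(
        self,
        gwas: pd.DataFrame,
        weight_models: list[WeightModel],
        ld_blocks: list[LDBlockMatrix],
        blocks: list[RegionDefinition],
        model_ld_cov: pd.DataFrame | None = None,
    ) -> None:
        self.gwas = gwas
        self.weight_models = weight_models
        self.ld_blocks = ld_blocks
        self.blocks = blocks
        self.model_ld_cov = model_ld_cov

    @classmethod
    def from_files(
        cls,
        sumstats: str | pathlib.Path,
        weights: str | pathlib.Path,
        ld_dir: str | pathlib.Path,
        blocks: str | pathlib.Path,
        weights_manifest: str | pathlib.Path | None = None,
        weight_cov: str | pathlib.Path | None = None,
    ) -> "CTWAS":
        return cls(
            gwas=ctwas_io.read_gwas_sumstats(sumstats),
            weight_models=ctwas_io.read_weight_models(weights, weights_manifest),
            ld_blocks=ctwas_io.read_ld_reference(ld_dir),
            blocks=ctwas_io.read_block_definitions(blocks),
            model_ld_cov=(
                ctwas_io.read_weight_covariances(weight_cov)
                if weight_cov else None
            ),
        )

    @classmethod
    def from_bundle(cls, bundle) -> "CTWAS":
        """Build directly from a :class:`ctwas.simulate.SimBundle`."""
        return cls(
            gwas=bundle.gwas,
            weight_models=bundle.weight_models,
            ld_blocks=bundle.ld_blocks,
            blocks=bundle.blocks,
        )

    def fit(self, config: PipelineConfig | None = None, **overrides
            ) -> "CTWASResults":
        """Estimate group priors and fine-map; returns a results object.

        Keyword overrides (e.g. ``seed=3``, ``thin=0.1``, ``L=5``) update
        the default :class:`PipelineConfig`.
        """
        if config is None:
            config = PipelineConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a config or keyword overrides")
        artifacts = run_ctwas(
            self.gwas, self.weight_models, self.ld_blocks, self.blocks,
            config=config, model_ld_cov=self.model_ld_cov,
        )
        return CTWASResults(self, config, artifacts)


class CTWASResults:
    """Fitted results: prior estimates, PIPs, credible sets, PVE."""

    def __init__(self, model: CTWAS, config: PipelineConfig,
                 artifacts: RunArtifacts) -> None:
        self.model = model
        self.config = config
        self._artifacts = artifacts
        self.results = artifacts.results
        self.priors = artifacts.theta
        self.pve = artifacts.pve
        self.fits = artifacts.fits
        self.rescued_regions = artifacts.rescued

    @property
    def genes(self) -> pd.DataFrame:
        return (
            self.results[self.results["type"] == "gene"]
            .sort_values("PIP", ascending=False)
            .reset_index(drop=True)
        )

    def significant_genes(self, pip_threshold: float | None = None
                          ) -> pd.DataFrame:
        thr = (self.config.pip_threshold if pip_threshold is None
               else pip_threshold)
        g = self.genes
        return g[g["PIP"] > thr].reset_index(drop=True)

    @property
    def credible_sets(self) -> pd.DataFrame:
        rows = []
        for rid, fit in sorted(self.fits.items()):
            for cs in fit.credible_sets:
                rows.append(
                    {
                        "cs_id": cs.cs_id,
                        "region_id": rid,
                        "n_members": len(cs.members),
                        "coverage": cs.coverage,
                        "purity": cs.purity,
                        "members": ",".join(cs.members),
                    }
                )
        return pd.DataFrame(
            rows, columns=["cs_id", "region_id", "n_members", "coverage",
                           "purity", "members"],
        )

    def summary(self) -> str:
        """Human-readable run summary."""
        th = self.priors
        pve = self.pve
        sig = self.significant_genes()
        n_gene = int((self.results["type"] == "gene").sum())
        n_var = int((self.results["type"] == "variant").sum())
        lines = [
            "cTWAS results",
            "=" * 60,
            f"variables analyzed: {n_gene} genes, {n_var} variants "
            f"({len(self.fits)} regions, {len(self.rescued_regions)} rescued)",
            "",
            "Group prior estimates (z-score scale)",
            f"  pi_gene       {th.pi_gene: .4e}",
            f"  pi_variant    {th.pi_variant: .4e}",
            f"  sigma2_gene   {th.sigma2_gene: .4f}",
            f"  sigma2_variant{th.sigma2_variant: .4f}",
            f"  enrichment (pi_gene/pi_variant): {th.enrichment:.2f}",
            "",
            "Variance explained",
            f"  PVE genes     {pve.pve_gene:.4f}",
            f"  PVE variants  {pve.pve_variant:.4f}",
            f"  total         {pve.total:.4f}",
            f"  attributable to expression: "
            f"{100 * pve.attributable_to_expression:.1f}%",
            "",
            f"genes with PIP > {self.config.pip_threshold}: {len(sig)}",
        ]
        for row in sig.head(20).itertuples():
            lines.append(f"  {row.variable_id:<20s} PIP={row.PIP:.3f} "
                         f"z={row.z: .2f}  region={row.region_id}")
        return "\n".join(lines)

    def save(self, out_dir: str | pathlib.Path) -> None:
        """Write the results table, priors and PVE report to a directory."""
        import yaml

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False)
        self.credible_sets.to_csv(out / "credible_sets.tsv", sep="\t",
                                  index=False)
        report = {
            "priors": self.priors.to_dict(),
            "pve": self.pve.to_dict(),
        }
        if self.priors.trajectory is not None:
            report["trajectory"] = {
                k: [float(x) for x in v]
                for k, v in self.priors.trajectory.to_dict("list").items()
            }
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)

    def plot_pip(self, ax=None):
        """Scatter of gene PIPs along the genome (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        g = self.genes
        ax.scatter(np.arange(len(g)), g["PIP"], s=8)
        ax.axhline(self.config.pip_threshold, color="red", ls="--", lw=0.8)
        ax.set_xlabel("gene rank")
        ax.set_ylabel("PIP")
        ax.set_ylim(0, 1.02)
        return ax
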