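"""Readers and writers for the on-disk formats the pipeline consumes.

* GWAS summary statistics: tab-delimited with header
  ``CHR POS A1 A2 (Z | BETA SE) N`` where A2 is the effect (alt) allele
  and A1 the other (ref) allele.
* Weight models: tab-delimited ``GENE CHR POS A1 A2 WEIGHT`` plus a YAML
  manifest declaring the weight scale and per-gene TSS, and an optional
  covariance table ``GENE VAR1 VAR2 COV`` for PredictDB-style ambiguity
  resolution.
* LD reference: one NPZ (or HDF5) matrix per block plus a sidecar
  variant table ``block_id CHR POS A1 A2 MAF``.
* LD block definitions: BED-like ``chrom start stop block_id``
  (0-based half-open on disk, converted to 1-based internally).
"""
from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .types import LDBlockMatrix, RegionDefinition, WeightModel, make_variant_id


def read_gwas_sumstats(path: str | pathlib.Path) -> pd.DataFrame:
    """Read GWAS summary statistics into the internal variant-table form.

    If BETA and SE are supplied instead of Z, z = beta/se is computed on
    read. Returns columns variant_id, chrom, pos, ref, alt, z, n_gwas.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = {"CHR", "POS", "A1", "A2", "N"}
    if not required.issubset(df.columns):
        raise ValueError(f"sumstats missing columns {required - set(df.columns)}")
    if "Z" in df.columns:
        z = df["Z"].astype(float)
    elif {"BETA", "SE"}.issubset(df.columns):
        z = df["BETA"].astype(float) / df["SE"].astype(float)
    else:
        raise ValueError("sumstats must provide Z or BETA+SE")
    out = pd.DataFrame(
        {
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(int),
            "ref": df["A1"].astype(str).str.upper(),
            "alt": df["A2"].astype(str).str.upper(),
            "z": z,
            "n_gwas": df["N"].astype(int),
        }
    )
    out.insert(
        0,
        "variant_id",
        [make_variant_id(c, p, r, a)
         for c, p, r, a in zip(out.chrom, out.pos, out.ref, out.alt)],
    )
    if not np.all(np.isfinite(out["z"])):
        raise ValueError("non-finite z-scores in sumstats")
    return out


def write_gwas_sumstats(df: pd.DataFrame, path: str | pathlib.Path) -> None:
    out = pd.DataFrame(
        {
            "CHR": df["chrom"],
            "POS": df["pos"],
            "A1": df["ref"],
            "A2": df["alt"],
            "Z": df["z"],
            "N": df["n_gwas"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_weight_models(
    weights_path: str | pathlib.Path,
    manifest_path: str | pathlib.Path | None = None,
) -> list[WeightModel]:
    """Read per-gene weight tables; the manifest declares the scale
    ("standardized" unless stated) and optionally per-gene TSS positions."""
    df = pd.read_csv(weights_path, sep="\t", dtype={"CHR": str})
    manifest: dict = {}
    if manifest_path is not None:
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh) or {}
    scale = manifest.get("scale", "standardized")
    tss = manifest.get("tss", {})
    models = []
    for gene_id, sub in df.groupby("GENE", sort=True):
        variants = pd.DataFrame(
            {
                "chrom": sub["CHR"].astype(str),
                "pos": sub["POS"].astype(int),
                "ref": sub["A1"].astype(str).str.upper(),
                "alt": sub["A2"].astype(str).str.upper(),
            }
        )
        variants.insert(
            0,
            "variant_id",
            [make_variant_id(c, p, r, a)
             for c, p, r, a in zip(
                 variants.chrom, variants.pos, variants.ref, variants.alt)],
        )
        chrom = variants["chrom"].iloc[0]
        models.append(
            WeightModel(
                gene_id=str(gene_id),
                chrom=chrom,
                tss_pos=int(tss.get(str(gene_id), variants["pos"].min())),
                variants=variants.reset_index(drop=True),
                weights=sub["WEIGHT"].to_numpy(dtype=float),
                scale=scale,
            )
        )
    return models


def write_weight_models(
    models: list[WeightModel],
    weights_path: str | pathlib.Path,
    manifest_path: str | pathlib.Path | None = None,
) -> None:
    rows = []
    for m in models:
        for (_, v), w in zip(m.variants.iterrows(), m.weights):
            rows.append((m.gene_id, v.chrom, v.pos, v.ref, v.alt, w))
    pd.DataFrame(
        rows, columns=["GENE", "CHR", "POS", "A1", "A2", "WEIGHT"]
    ).to_csv(weights_path, sep="\t", index=False)
    if manifest_path is not None:
        manifest = {
            "scale": models[0].scale if models else "standardized",
            "tss": {m.gene_id: int(m.tss_pos) for m in models},
        }
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh)


def read_weight_covariances(path: str | pathlib.Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"GENE", "VAR1", "VAR2", "COV"}
    if not required.issubset(df.columns):
        raise ValueError(f"covariance table missing {required - set(df.columns)}")
    return df


def read_ld_reference(
    ld_dir: str | pathlib.Path, sidecar: str | pathlib.Path | None = None
) -> list[LDBlockMatrix]:
    """Read an LD reference: one ``<block_id>.npz`` per block (array under
    key "corr") and a sidecar variant table ``ld_variants.tsv``."""
    ld_dir = pathlib.Path(ld_dir)
    sidecar = pathlib.Path(sidecar) if sidecar else ld_dir / "ld_variants.tsv"
    meta = pd.read_csv(sidecar, sep="\t", dtype={"CHR": str})
    blocks = []
    for block_id, sub in meta.groupby("block_id", sort=True):
        npz = np.load(ld_dir / f"{block_id}.npz")
        variants = pd.DataFrame(
            {
                "chrom": sub["CHR"].astype(str),
                "pos": sub["POS"].astype(int),
                "ref": sub["A1"].astype(str).str.upper(),
                "alt": sub["A2"].astype(str).str.upper(),
                "maf": sub["MAF"].astype(float),
            }
        )
        variants.insert(
            0,
            "variant_id",
            [make_variant_id(c, p, r, a)
             for c, p, r, a in zip(
                 variants.chrom, variants.pos, variants.ref, variants.alt)],
        )
        blocks.append(
            LDBlockMatrix(
                block_id=str(block_id),
                variants=variants.reset_index(drop=True),
                corr=npz["corr"],
            )
        )
    return blocks


def write_ld_reference(
    blocks: list[LDBlockMatrix], ld_dir: str | pathlib.Path
) -> None:
    ld_dir = pathlib.Path(ld_dir)
    ld_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for blk in blocks:
        np.savez_compressed(ld_dir / f"{blk.block_id}.npz", corr=blk.corr)
        t = blk.variants
        for _, v in t.iterrows():
            rows.append(
                (blk.block_id, v.chrom, v.pos, v.ref, v.alt, v.get("maf", np.nan))
            )
    pd.DataFrame(
        rows, columns=["block_id", "CHR", "POS", "A1", "A2", "MAF"]
    ).to_csv(ld_dir / "ld_variants.tsv", sep="\t", index=False)


def read_block_definitions(path: str | pathlib.Path) -> list[RegionDefinition]:
    """Read BED-like block definitions (0-based half-open) into 1-based
    half-open RegionDefinitions."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "stop", "block_id"],
        dtype={"chrom": str},
        comment="#",
    )
    return [
        RegionDefinition(
            region_id=str(r.block_id),
            chrom=str(r.chrom),
            start=int(r.start) + 1,
            stop=int(r.stop) + 1,
            member_block_ids=[str(r.block_id)],
        )
        for r in df.itertuples()
    ]


def write_block_definitions(
    blocks: list[RegionDefinition], path: str | pathlib.Path
) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.stop - 1}\t{b.region_id}\n")
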