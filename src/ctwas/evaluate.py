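"""Scoring of method output against simulation truth, the TWAS baseline,
the silver-standard precision metric, and attribution of TWAS false
positives to their source of genetic confounding."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import SusieFit


def calibration_table(
    pips: np.ndarray,
    truth: np.ndarray,
    bin_edges: np.ndarray | None = None,
    replicate: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin variables by PIP and compare mean PIP to the causal fraction.

    Returns per-bin mean PIP, empirical fraction truly causal, count,
    and (when ``replicate`` labels are given) the standard error of the
    causal fraction across replicates.
    """
    pips = np.asarray(pips, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    idx = np.clip(np.digitize(pips, bin_edges) - 1, 0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append((bin_edges[b], bin_edges[b + 1], 0, np.nan, np.nan,
                         np.nan))
            continue
        mean_pip = float(pips[sel].mean())
        frac = float(truth[sel].mean())
        se = np.nan
        if replicate is not None:
            reps = np.asarray(replicate)[sel]
            per_rep = [
                truth[sel][reps == r].mean() for r in np.unique(reps)
                if (reps == r).sum() > 0
            ]
            if len(per_rep) > 1:
                se = float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep)))
        rows.append((bin_edges[b], bin_edges[b + 1], n, mean_pip, frac, se))
    return pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "count", "mean_pip", "frac_causal",
                 "se_frac"],
    )


def fdp_power(
    pips: np.ndarray, truth: np.ndarray, threshold: float = 0.8
) -> tuple[float, float, int]:
    """False discovery proportion and power at a PIP threshold."""
    pips = np.asarray(pips, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    detected = pips > threshold
    n_det = int(detected.sum())
    n_false = int((detected & ~truth).sum())
    n_causal = int(truth.sum())
    fdp = n_false / max(n_det, 1)
    power = int((detected & truth).sum()) / n_causal if n_causal else 0.0
    return fdp, power, n_det


def twas_baseline(
    gene_z: pd.Series | dict, n_genes: int | None = None, alpha: float = 0.05
) -> set[str]:
    """Bonferroni-significant genes from marginal TWAS z-scores."""
    z = pd.Series(gene_z, dtype=float)
    m = n_genes if n_genes is not None else len(z)
    p = 2.0 * norm.sf(np.abs(z))
    return set(z.index[p < alpha / m])


def precision(detected: set, positives: set, negatives: set) -> float:
    """Silver-standard precision: detected positives over detected
    positives plus detected negatives; detections outside both sets are
    ignored. NaN when no detection falls in either set."""
    if positives & negatives:
        raise ValueError("positive and negative sets overlap")
    tp = len(detected & positives)
    fp = len(detected & negatives)
    if tp + fp == 0:
        return float("nan")
    return tp / (tp + fp)


@dataclass
class AttributionResult:
    gene_id: str
    verdict: str  # confounded_by_genes | confounded_by_variants | unassigned
    credible_set_id: str = ""
    competing_gene_pip: float = 0.0
    competing_variant_pip: float = 0.0


def attribute_false_positives(
    twas_significant: set[str],
    fits: dict[str, SusieFit],
    region_corr: dict[str, np.ndarray],
    pip_cutoff: float = 0.5,
    r_cutoff: float = 0.5,
) -> list[AttributionResult]:
    """Classify TWAS-significant, low-PIP genes by confounding source.

    A false positive (TWAS-significant gene with PIP < ``pip_cutoff``)
    is assigned to a credible set it belongs to, or failing that to any
    set containing a variable it is correlated with at |r| >
    ``r_cutoff``. The summed PIPs of the set's other genes vs variants
    decide the verdict, variants winning ties; genes assignable to no
    set are ``unassigned``.
    """
    out = []
    for rid, fit in sorted(fits.items()):
        pip = fit.pip
        idx_of = {vid: j for j, vid in enumerate(fit.variable_ids)}
        corr = region_corr.get(rid)
        for gid in sorted(twas_significant):
            j = idx_of.get(gid)
            if j is None or fit.group_labels[j] != "gene":
                continue
            if pip[j] >= pip_cutoff:
                continue
            assigned = None
            for cs in fit.credible_sets:
                if gid in cs.members:
                    assigned = cs
                    break
            if assigned is None and corr is not None:
                for cs in fit.credible_sets:
                    m_idx = [idx_of[m] for m in cs.members if m != gid]
                    if m_idx and np.max(np.abs(corr[j, m_idx])) > r_cutoff:
                        assigned = cs
                        break
            if assigned is None:
                out.append(AttributionResult(gene_id=gid, verdict="unassigned"))
                continue
            others = [m for m in assigned.members if m != gid]
            g_sum = sum(
                pip[idx_of[m]] for m in others
                if fit.group_labels[idx_of[m]] == "gene"
            )
            v_sum = sum(
                pip[idx_of[m]] for m in others
                if fit.group_labels[idx_of[m]] == "variant"
            )
            verdict = (
                "confounded_by_genes" if g_sum > v_sum
                else "confounded_by_variants"
            )
            out.append(
                AttributionResult(
                    gene_id=gid, verdict=verdict, credible_set_id=assigned.cs_id,
                    competing_gene_pip=float(g_sum),
                    competing_variant_pip=float(v_sum),
                )
            )
    return out


def score_run(
    results: pd.DataFrame,
    causal_genes: set[str],
    pip_threshold: float = 0.8,
) -> dict:
    """Convenience scorer for one simulated run's gene results."""
    genes = results[results["type"] == "gene"]
    truth = genes["variable_id"].isin(causal_genes).to_numpy()
    fdp, power, n_det = fdp_power(
        genes["PIP"].to_numpy(), truth, threshold=pip_threshold
    )
    return {
        "n_genes": len(genes),
        "n_causal": int(truth.sum()),
        "n_detected": n_det,
        "fdp": fdp,
        "power": power,
    }
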