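"""Differential expression of genes and TE families across mutant contrasts.

Counts are modeled as negative binomial with variance mu + alpha*mu^2.
Library depth is removed with median-of-ratios size factors; per-feature
dispersion is estimated by method of moments from within-group variances
and then shrunk toward the experiment-wide mean dispersion, weighting the
per-feature estimate by its residual degrees of freedom against a prior
weight. With three replicates per side a raw per-feature moment estimate is
far too noisy to plug into a Wald statistic — chance under-estimates
inflate the test badly — so the moderation plays the same stabilizing role
as the dispersion shrinkage in standard count-based DE packages. The group
contrast is a Wald test on the log fold change with a normal reference.

Calls use strict thresholds — FDR < 0.05 (Benjamini-Hochberg) and
|log2 fold change| > 1 — and downstream analysis keeps only features called
in the same direction in at least two mutant contrasts of the same pathway
(CMT or RdDM). Genes within 40 Mb of a backcrossed mutation locus are
excluded as linked: introgressed flanking segments carry cis-regulatory
variants that masquerade as methylation effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel

LOG2FC_CUTOFF = 1.0
FDR_CUTOFF = 0.05
LINKED_WINDOW_BP = 40_000_000
DE_BIN_SIZE = 2_000_000
DISPERSION_FLOOR = 1e-8
DISPERSION_PRIOR_WEIGHT = 20.0  # pseudo-df of the trend in the shrinkage
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Contrast:
    name: str
    mutant_libs: tuple[str, ...]
    control_libs: tuple[str, ...]
    pathway: str  # "CMT" or "RdDM"
    mutated_locus: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.mutant_libs) < 2 or len(self.control_libs) < 2:
            raise ValueError(
                f"contrast {self.name}: need ≥2 libraries per side for dispersion"
            )
        if self.pathway not in {"CMT", "RdDM"}:
            raise ValueError(f"contrast {self.name}: unknown pathway {self.pathway!r}")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Computed over features with all-positive counts; if none exist, falls
    back to total-count ratios against their geometric mean.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        totals = counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty library")
        return totals / stats.gmean(totals)
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0))


def nb_test(counts: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-feature NB Wald test for one mutant-vs-control contrast.

    Returns a DataFrame indexed by feature with columns log2fc, p,
    base_mean. Features with zero counts in both groups get log2fc 0 and
    p 1.
    """
    libs = list(contrast.mutant_libs) + list(contrast.control_libs)
    missing = [l for l in libs if l not in counts.columns]
    if missing:
        raise ValueError(f"contrast {contrast.name}: libraries not in table: {missing}")
    sf = size_factors(counts[libs])
    q = counts[libs].div(sf, axis=1)
    qm = q[list(contrast.mutant_libs)].to_numpy(float)
    qc = q[list(contrast.control_libs)].to_numpy(float)
    n1, n2 = qm.shape[1], qc.shape[1]

    m1 = qm.mean(axis=1)
    m2 = qc.mean(axis=1)
    v1 = qm.var(axis=1, ddof=1)
    v2 = qc.var(axis=1, ddof=1)
    # method-of-moments dispersion from pooled within-group variance,
    # shrunk toward the experiment-wide mean dispersion (df-weighted)
    df_data = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_data
    m_pool = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (s2 - m_pool) / np.square(m_pool)
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, np.nan)
    informative = ~np.isnan(alpha_mom) & (m_pool > 5)
    if informative.any():
        alpha_trend = max(float(np.nanmean(alpha_mom[informative])), 0.0)
    else:
        alpha_trend = 0.0
    alpha_feat = np.where(np.isnan(alpha_mom), alpha_trend, np.clip(alpha_mom, 0, None))
    alpha = (DISPERSION_PRIOR_WEIGHT * alpha_trend + df_data * alpha_feat) / (
        DISPERSION_PRIOR_WEIGHT + df_data
    )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT))
    var_ln = (m1 + alpha * m1**2) / (n1 * (m1 + PSEUDOCOUNT) ** 2) + (
        m2 + alpha * m2**2
    ) / (n2 * (m2 + PSEUDOCOUNT) ** 2)
    se_ln = np.sqrt(var_ln)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc * np.log(2.0) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))

    all_zero = (m1 == 0) & (m2 == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": np.clip(p, 0.0, 1.0),
            "base_mean": m_pool,
        },
        index=counts.index,
    )


def adjust_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone in rank)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
) -> pd.DataFrame:
    """Attach BH FDR and up/down/ns calls with strict cutoffs."""
    out = results.copy()
    out["fdr"] = adjust_fdr(out["p"].to_numpy())
    call = np.full(len(out), "ns", dtype=object)
    sig = out["fdr"].to_numpy() < fdr_cutoff
    lfc = out["log2fc"].to_numpy()
    call[sig & (lfc > log2fc_cutoff)] = "up"
    call[sig & (lfc < -log2fc_cutoff)] = "down"
    out["call"] = call
    return out


def exclude_linked(
    de: pd.DataFrame,
    contrast: Contrast,
    genes: Mapping[str, GeneModel],
    window_bp: int = LINKED_WINDOW_BP,
) -> pd.DataFrame:
    """Reset DE genes within ``window_bp`` of the mutation locus to ns.

    Only gene features with a known position are considered; TE families
    (absent from ``genes``) pass through untouched, as does everything when
    the contrast has no declared locus (a non-introgressed background).
    Excluded rows get reason "linked".
    """
    out = de.copy()
    if "reason" not in out.columns:
        out["reason"] = ""
    if contrast.mutated_locus is None:
        import logging

        logging.getLogger(__name__).warning(
            "contrast %s has no mutated locus; linked-gene exclusion skipped",
            contrast.name,
        )
        return out
    chrom, locus = contrast.mutated_locus
    for feature in out.index:
        gene = genes.get(feature)
        if gene is None or gene.chrom != chrom:
            continue
        if out.at[feature, "call"] == "ns":
            continue
        if abs(gene.midpoint - locus) < window_bp:
            out.at[feature, "call"] = "ns"
            out.at[feature, "reason"] = "linked"
    return out


def consistent_de(
    per_contrast: Mapping[str, pd.DataFrame],
    contrast_pathways: Mapping[str, str],
    min_contrasts: int = 2,
) -> dict[str, dict[str, set[str]]]:
    """Features called in the same direction in ≥2 contrasts of a pathway.

    Returns {pathway: {"up": set, "down": set}}. Opposite-direction calls
    never merge: a feature up in one contrast and down in another counts
    toward neither set.
    """
    pathways = sorted(set(contrast_pathways.values()))
    result = {pw: {"up": set(), "down": set()} for pw in pathways}
    for pw in pathways:
        names = [c for c, p in contrast_pathways.items() if p == pw]
        if len(names) < min_contrasts:
            raise ValueError(
                f"pathway {pw}: need ≥{min_contrasts} contrasts, got {len(names)}"
            )
        for direction in ("up", "down"):
            tallies: dict[str, int] = {}
            for name in names:
                de = per_contrast[name]
                for feature in de.index[de["call"] == direction]:
                    tallies[feature] = tallies.get(feature, 0) + 1
            result[pw][direction] = {
                f for f, n in tallies.items() if n >= min_contrasts
            }
    return result


def bin_de_counts(
    de_genes: Iterable[str],
    genes: Mapping[str, GeneModel],
    chrom_lengths: Mapping[str, int],
    bin_size: int = DE_BIN_SIZE,
) -> pd.DataFrame:
    """Count DE genes per non-overlapping genomic bin, assigned by midpoint."""
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        n_bins = int(np.ceil(length / bin_size)) if length > 0 else 0
        for i in range(n_bins):
            rows.append({"chrom": chrom, "bin_start": i * bin_size, "n_de": 0})
    table = pd.DataFrame(rows)
    index = {(r.chrom, r.bin_start): i for i, r in enumerate(table.itertuples())}
    for gid in de_genes:
        g = genes[gid]
        b = int(g.midpoint // bin_size) * bin_size
        table.loc[index[(g.chrom, b)], "n_de"] += 1
    return table
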