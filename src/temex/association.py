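"""Relating differential expression to DNA methylation features.

Covers the descriptive and statistical links between the DE sets and the
methylome: strand-aware methylation metaprofiles around the TSS and TTS,
classification of genes by methylation in the first 400 bp downstream of
the TSS (the window where CHG-silenced genes show a bimodal high/low
split), proximity of genes and TEs to mCHH islands (within the feature or
2 kb around it) and of DMRs to the TSS (±200 bp), chi-squared enrichment of
such flags in a gene set against a background, and the Pearson correlation
between methylation at a DMR and transcript abundance across a genotype
panel — the signature of a natural epiallele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .methylation import TILE_SIZE, DMRCatalogEntry, MCHHIsland

FLANK_BP = 2000
TSS_WINDOW_BP = 400
ISLAND_PROXIMITY_BP = 2000
DMR_TSS_WINDOW_BP = 200
TSS_HIGH_LEVEL = 0.50
TSS_LOW_LEVEL = 0.20
ENRICHMENT_P = 0.01
CORRELATION_P = 0.05


def _window_level(
    tiles: pd.DataFrame, chrom: str, start: int, end: int, context: str
) -> tuple[float, float] | None:
    """Read-weighted methylation level over [start, end), or None if uncovered.

    Tiles partially overlapping the window contribute reads in proportion to
    their overlap fraction. Returns (level, effective_reads).
    """
    sub = tiles[
        (tiles["chrom"] == chrom)
        & (tiles["context"] == context)
        & (tiles["tile_start"] < end)
        & (tiles["tile_start"] + TILE_SIZE > start)
    ]
    if len(sub) == 0:
        return None
    overlap = (
        np.minimum(sub["tile_start"] + TILE_SIZE, end)
        - np.maximum(sub["tile_start"], start)
    ) / TILE_SIZE
    total = float((sub["total_reads"] * overlap).sum())
    if total <= 0:
        return None
    mc = float((sub["mc_reads"] * overlap).sum())
    return mc / total, total


def metaprofile(
    genes: Mapping[str, GeneModel],
    tiles: pd.DataFrame,
    gene_set: Iterable[str],
    context: str,
    flank_bp: int = FLANK_BP,
) -> pd.DataFrame:
    """Strand-aware mean ± SE methylation profile around the TSS and TTS.

    For each gene the flanking ``flank_bp`` and the adjacent gene-body side
    are sampled in 100-bp bins anchored at the TSS and at the TTS (profiles
    of − strand genes are flipped so that negative offsets are always
    upstream in the transcriptional sense). Returns a tidy frame with
    columns anchor ∈ {TSS, TTS}, offset (bin start relative to anchor),
    mean, se, n_genes. Bins a gene does not cover (body shorter than the
    window) are skipped for that gene.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    n_bins = flank_bp // TILE_SIZE
    offsets = [i * TILE_SIZE for i in range(-n_bins, n_bins)]
    acc: dict[tuple[str, int], list[float]] = {
        (anchor, off): [] for anchor in ("TSS", "TTS") for off in offsets
    }
    for gid in gene_set:
        g = genes[gid]
        length = g.end - g.start
        for anchor, pos in (("TSS", g.tss), ("TTS", g.tts)):
            for off in offsets:
                # offset in transcription direction; body bins must lie
                # within the gene span
                into_body = (anchor == "TSS" and off >= 0) or (
                    anchor == "TTS" and off < 0
                )
                if into_body and abs(off if off >= 0 else off + TILE_SIZE) > length:
                    continue
                if g.strand == "+":
                    w0 = pos + off
                else:
                    w0 = pos - off - TILE_SIZE
                res = _window_level(tiles, g.chrom, w0, w0 + TILE_SIZE, context)
                if res is not None:
                    acc[(anchor, off)].append(res[0])
    rows = []
    for (anchor, off), values in acc.items():
        if values:
            arr = np.asarray(values)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            rows.append(
                {
                    "anchor": anchor,
                    "offset": off,
                    "context": context,
                    "mean": arr.mean(),
                    "se": se,
                    "n_genes": len(arr),
                }
            )
        else:
            rows.append(
                {
                    "anchor": anchor,
                    "offset": off,
                    "context": context,
                    "mean": np.nan,
                    "se": np.nan,
                    "n_genes": 0,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["anchor", "offset"])
        .reset_index(drop=True)
    )


def tss_methylation_class(
    gene: GeneModel,
    tiles: pd.DataFrame,
    context: str,
    window_bp: int = TSS_WINDOW_BP,
) -> str:
    """Classify a gene by methylation in the first 400 bp past its TSS.

    Read-weighted mean over the window in the transcribed direction;
    high if > 50%, low if < 20%, intermediate between, no_data when no
    site is covered.
    """
    if gene.strand == "+":
        start, end = gene.tss, gene.tss + window_bp
    else:
        start, end = gene.tss - window_bp, gene.tss
    res = _window_level(tiles, gene.chrom, start, end, context)
    if res is None:
        return "no_data"
    level = res[0]
    if level > TSS_HIGH_LEVEL:
        return "high"
    if level < TSS_LOW_LEVEL:
        return "low"
    return "intermediate"


def island_proximity(
    features: Mapping[str, tuple[str, int, int]],
    islands: Sequence[MCHHIsland],
    flank_bp: int = ISLAND_PROXIMITY_BP,
) -> dict[str, bool]:
    """Flag features with an mCHH island inside or within 2 kb of their span.

    ``features`` maps id → (chrom, start, end); an island tile counts if it
    intersects [start − flank, end + flank).
    """
    by_chrom: dict[str, list[int]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl.tile_start)
    flags = {}
    for fid, (chrom, start, end) in features.items():
        lo, hi = start - flank_bp, end + flank_bp
        flags[fid] = any(
            t < hi and t + TILE_SIZE > lo for t in by_chrom.get(chrom, ())
        )
    return flags


def dmr_near_tss(
    genes: Mapping[str, GeneModel],
    catalog: Sequence[DMRCatalogEntry],
    window_bp: int = DMR_TSS_WINDOW_BP,
) -> pd.DataFrame:
    """Per-gene, per-context flags for a DMR tile within ±200 bp of the TSS."""
    by_key: dict[tuple[str, str], list[int]] = {}
    contexts = sorted({e.context for e in catalog}) or ["CG", "CHG", "CHH"]
    for e in catalog:
        by_key.setdefault((e.chrom, e.context), []).append(e.tile_start)
    rows = {}
    for gid, g in genes.items():
        lo, hi = g.tss - window_bp, g.tss + window_bp
        rows[gid] = {
            ctx: any(
                t < hi and t + TILE_SIZE > lo
                for t in by_key.get((g.chrom, ctx), ())
            )
            for ctx in contexts
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def enrichment_test(
    set_flags: Sequence[bool],
    background_flags: Sequence[bool],
    p_cutoff: float = ENRICHMENT_P,
) -> tuple[float, float, bool]:
    """Chi-squared test (no continuity correction) of flag enrichment.

    Returns (chi2, p, enriched) where enriched additionally requires the
    set's flagged proportion to exceed the background's.
    """
    set_flags = np.asarray(set_flags, dtype=bool)
    background_flags = np.asarray(background_flags, dtype=bool)
    if len(set_flags) == 0 or len(background_flags) == 0:
        raise ValueError("both groups must be nonempty")
    table = np.array(
        [
            [set_flags.sum(), (~set_flags).sum()],
            [background_flags.sum(), (~background_flags).sum()],
        ],
        dtype=float,
    )
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError(
            "zero expected count in the 2x2 table; an exact test would be needed"
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    enriched = bool(p < p_cutoff and set_flags.mean() > background_flags.mean())
    return float(chi2), float(p), enriched


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    significant: bool
    defined: bool


def methylation_expression_correlation(
    methylation: Sequence[float],
    expression: Sequence[float],
    p_cutoff: float = CORRELATION_P,
) -> CorrelationResult:
    """Pearson correlation of DMR methylation vs expression across a panel.

    Needs at least 4 genotypes with both measurements. Zero variance in
    either vector leaves r undefined (flagged, never significant).
    """
    m = np.asarray(methylation, dtype=float)
    e = np.asarray(expression, dtype=float)
    if m.shape != e.shape:
        raise ValueError("methylation and expression vectors differ in length")
    keep = np.isfinite(m) & np.isfinite(e)
    m, e = m[keep], e[keep]
    if len(m) < 4:
        raise ValueError(f"need ≥4 genotypes with both values, got {len(m)}")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        return CorrelationResult(np.nan, np.nan, False, False)
    r, p = stats.pearsonr(m, e)
    return CorrelationResult(float(r), float(p), bool(p < p_cutoff), True)
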