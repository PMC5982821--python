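"""Tile-based methylome summaries, DMR calling, and mCHH islands.

Per-cytosine methylation calls (methratio-style: chrom, position, strand,
context, methylated reads, total reads) are pooled into non-overlapping
100-bp tiles separately for the CG, CHG and CHH contexts. Tile level is the
read-weighted ratio sum(mC reads)/sum(total reads) over all called
cytosines in the tile; each called cytosine is its own site (symmetric
CG/CHG positions are not collapsed across strands).

Differentially methylated regions between two genotypes require, in both
genotypes, more than 6 context sites in the tile and mean per-site coverage
above 2x. CG/CHG DMRs additionally need a methylation difference above 60
percentage points; CHH DMRs — reflecting the genome's low CHH baseline —
need one genotype below 5% and the other above 25%. mCHH islands are tiles
with CHH methylation strictly above 25% backed by at least 10 informative
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TILE_SIZE = 100
CONTEXTS = ("CG", "CHG", "CHH")

# DMR gates, per genotype
DMR_MIN_SITES = 6          # strictly more than this many sites
DMR_MIN_COVERAGE = 2.0     # strictly more than this mean reads/site
DMR_CG_CHG_DIFF = 60.0     # strictly more than this many percentage points
DMR_CHH_LOW = 0.05         # strictly below in one genotype
DMR_CHH_HIGH = 0.25        # strictly above in the other

ISLAND_MIN_LEVEL = 0.25    # strictly above
ISLAND_MIN_READS = 10      # at least this many informative reads

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "mc_reads", "total_reads"]


def tile_methylation(
    calls: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Summarize per-cytosine calls into per-context 100-bp tiles.

    Returns a DataFrame with columns chrom, tile_start, context, n_sites,
    mc_reads, total_reads, level, mean_site_coverage. Both strands are
    pooled; the final partial tile of each chromosome is retained. Tiles
    with no covered site simply do not appear (level undefined).
    """
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if len(calls) == 0:
        return pd.DataFrame(
            columns=["chrom", "tile_start", "context", "n_sites", "mc_reads",
                     "total_reads", "level", "mean_site_coverage"]
        )
    for chrom, grp in calls.groupby("chrom", observed=True):
        if chrom not in chrom_lengths:
            raise ValueError(f"calls on unknown chromosome {chrom!r}")
        bad = grp["pos"] >= chrom_lengths[chrom]
        if bad.any():
            pos = int(grp.loc[bad, "pos"].iloc[0])
            raise ValueError(
                f"position {pos} beyond chromosome {chrom} "
                f"length {chrom_lengths[chrom]}"
            )
    if (calls["mc_reads"] > calls["total_reads"]).any():
        raise ValueError("mc_reads exceeds total_reads")

    df = calls.copy()
    df["tile_start"] = (df["pos"] // TILE_SIZE) * TILE_SIZE
    grouped = df.groupby(["chrom", "tile_start", "context"], observed=True)
    tiles = grouped.agg(
        n_sites=("pos", "nunique"),
        mc_reads=("mc_reads", "sum"),
        total_reads=("total_reads", "sum"),
    ).reset_index()
    tiles = tiles[tiles["total_reads"] > 0].copy()
    tiles["level"] = tiles["mc_reads"] / tiles["total_reads"]
    tiles["mean_site_coverage"] = tiles["total_reads"] / tiles["n_sites"]
    return tiles.sort_values(["chrom", "tile_start", "context"]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class DMRCall:
    chrom: str
    tile_start: int
    context: str
    genotype_a: str
    genotype_b: str
    level_a: float
    level_b: float

    @property
    def difference(self) -> float:
        """Absolute methylation difference in percentage points."""
        return abs(self.level_a - self.level_b) * 100.0


def _validate_grid(tiles: pd.DataFrame) -> None:
    if len(tiles) and (tiles["tile_start"] % TILE_SIZE != 0).any():
        raise ValueError("tile grid mismatch: tile_start not on the 100-bp grid")


def call_dmrs(
    tiles_a: pd.DataFrame,
    tiles_b: pd.DataFrame,
    context: str,
    genotype_a: str = "A",
    genotype_b: str = "B",
) -> list[DMRCall]:
    """Call DMRs of one context between two genotypes on a shared tile grid.

    The site-count and coverage gates must hold in both genotypes; tiles
    covered in only one genotype are never called. Calling is symmetric in
    the order of the genotypes.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    _validate_grid(tiles_a)
    _validate_grid(tiles_b)
    a = tiles_a[tiles_a["context"] == context]
    b = tiles_b[tiles_b["context"] == context]
    merged = a.merge(
        b, on=["chrom", "tile_start", "context"], suffixes=("_a", "_b")
    )
    if len(merged) == 0:
        return []
    gates = (
        (merged["n_sites_a"] > DMR_MIN_SITES)
        & (merged["n_sites_b"] > DMR_MIN_SITES)
        & (merged["mean_site_coverage_a"] > DMR_MIN_COVERAGE)
        & (merged["mean_site_coverage_b"] > DMR_MIN_COVERAGE)
    )
    # strict decimal boundaries: round away float representation error so a
    # difference of exactly 60.0 points is never called
    la = np.round(merged["level_a"], 9)
    lb = np.round(merged["level_b"], 9)
    if context in ("CG", "CHG"):
        hit = np.round((la - lb).abs() * 100.0, 9) > DMR_CG_CHG_DIFF
    else:
        hit = ((la < DMR_CHH_LOW) & (lb > DMR_CHH_HIGH)) | (
            (lb < DMR_CHH_LOW) & (la > DMR_CHH_HIGH)
        )
    called = merged[gates & hit]
    return [
        DMRCall(
            chrom=row.chrom,
            tile_start=int(row.tile_start),
            context=context,
            genotype_a=genotype_a,
            genotype_b=genotype_b,
            level_a=float(row.level_a),
            level_b=float(row.level_b),
        )
        for row in called.itertuples()
    ]


@dataclass(frozen=True)
class MCHHIsland:
    chrom: str
    tile_start: int
    genotype: str
    chh_level: float
    informative_reads: int


def call_mchh_islands(tiles: pd.DataFrame, genotype: str = "") -> list[MCHHIsland]:
    """Tiles with CHH level strictly above 25% and ≥10 informative reads."""
    chh = tiles[tiles["context"] == "CHH"]
    called = chh[
        (np.round(chh["level"], 9) > ISLAND_MIN_LEVEL)
        & (chh["total_reads"] >= ISLAND_MIN_READS)
    ]
    return [
        MCHHIsland(
            chrom=row.chrom,
            tile_start=int(row.tile_start),
            genotype=genotype,
            chh_level=float(row.level),
            informative_reads=int(row.total_reads),
        )
        for row in called.itertuples()
    ]


@dataclass
class DMRCatalogEntry:
    chrom: str
    tile_start: int
    context: str
    pairs: list[tuple[str, str]] = field(default_factory=list)


def pairwise_panel_dmrs(
    reference_tiles: pd.DataFrame,
    panel_tiles: Mapping[str, pd.DataFrame],
    reference_name: str = "reference",
    contexts: Sequence[str] = CONTEXTS,
) -> list[DMRCatalogEntry]:
    """Union of reference-vs-each pairwise DMRs, deduplicated by tile+context.

    Each catalog entry records every genotype pair in which the tile was
    called, so a DMR segregating in several panel members appears once.
    """
    if len(panel_tiles) < 1:
        raise ValueError("panel must contain at least one non-reference genotype")
    catalog: dict[tuple[str, int, str], DMRCatalogEntry] = {}
    for genotype, tiles in panel_tiles.items():
        for context in contexts:
            for dmr in call_dmrs(
                reference_tiles, tiles, context, reference_name, genotype
            ):
                key = (dmr.chrom, dmr.tile_start, dmr.context)
                entry = catalog.setdefault(
                    key, DMRCatalogEntry(dmr.chrom, dmr.tile_start, dmr.context)
                )
                entry.pairs.append((reference_name, genotype))
    return sorted(catalog.values(), key=lambda e: (e.chrom, e.tile_start, e.context))


def tiles_to_bedgraph(tiles: pd.DataFrame, context: str, path: str) -> None:
    sub = tiles[tiles["context"] == context]
    with open(path, "w") as fh:
        for row in sub.itertuples():
            fh.write(
                f"{row.chrom}\t{row.tile_start}\t{row.tile_start + TILE_SIZE}\t"
                f"{row.level:.4f}\n"
            )


def dmrs_to_bed(dmrs: Sequence[DMRCall], path: str) -> None:
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda x: (x.chrom, x.tile_start, x.context)):
            fh.write(
                f"{d.chrom}\t{d.tile_start}\t{d.tile_start + TILE_SIZE}\t"
                f"{d.context}\t{d.difference:.1f}\t.\n"
            )


def islands_to_bed(islands: Sequence[MCHHIsland], path: str) -> None:
    with open(path, "w") as fh:
        for i in sorted(islands, key=lambda x: (x.chrom, x.tile_start)):
            fh.write(
                f"{i.chrom}\t{i.tile_start}\t{i.tile_start + TILE_SIZE}\t"
                f"mCHH\t{i.chh_level:.3f}\t.\n"
            )
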