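"""Seeded toy-genome generators with planted ground truth.

Every downstream stage is validated against data generated here: a small
multi-chromosome genome with non-overlapping gene models; multi-copy TE
families (including helitrons, nested insertions and one element overlapping
a gene exon) whose copies are conceptually exact sequence duplicates, so a
read from a family member aligns equally well to every copy — one reported
hit per copy, which exercises the unique/multi assignment logic without
simulating an aligner; negative-binomial count tables with planted fold
changes; and per-cytosine methylation calls with context-specific background
levels, planted DMR tiles and planted mCHH islands.

All generators are fully deterministic under the config seed; substreams
are derived per stage so adding reads to one stage never reshuffles another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    ResolvedAnnotation,
    TEElement,
    LTR_SUPERFAMILIES,
)
from .quantify import AlignmentRecord

NON_HELITRON_SUPERFAMILIES = (
    "RLG", "RLC", "RLX", "DTA", "DTM", "DTC", "DTT", "DTH",
)

FRAGMENT_BP = 150
MATE_BP = 75

# WGBS backgrounds per context (typical maize genome-wide levels)
BACKGROUND_LEVELS = {"CG": 0.80, "CHG": 0.65, "CHH": 0.02}
SITES_PER_TILE = {"CG": 8, "CHG": 8, "CHH": 12}


@dataclass
class SyntheticConfig:
    """Study conditions for the toy genome and its libraries."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 300_000
    n_genes: int = 60
    n_te_families: int = 20
    copies_per_family: int = 4
    helitron_fraction: float = 0.05
    nested_te_fraction: float = 0.10
    n_libraries_per_genotype: int = 3
    planted_log2fc: float = 2.0
    dmr_spec: list[tuple[str, int, str, float, float]] | None = None
    island_spec: list[tuple[str, int, float]] | None = None
    read_depth: int = 50_000
    dispersion: float = 0.1
    coverage_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("helitron_fraction", "nested_te_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.copies_per_family < 1:
            raise ValueError("copies_per_family must be ≥ 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)
        }

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Planted structure against which recovery is scored."""

    de_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    dmrs: list[tuple[str, int, str, float, float]] = field(default_factory=list)
    islands: list[tuple[str, int, float]] = field(default_factory=list)
    epiallele_genes: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            de_features={k: tuple(v) for k, v in raw["de_features"].items()},
            dmrs=[tuple(d) for d in raw["dmrs"]],
            islands=[tuple(i) for i in raw["islands"]],
            epiallele_genes=raw.get("epiallele_genes", {}),
        )


# ---------------------------------------------------------------------------
# Genome and annotation


def generate_genome_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], list[TEElement], TruthSet]:
    """Place genes and TE families on the toy genome and plant the truth.

    Guarantees at least one helitron, one nested element pair, and one TE
    overlapping a gene exon. Non-helitron element count is exactly
    n_te_families × copies_per_family.
    """
    if config.n_te_families == 0:
        raise ValueError("nothing to annotate: n_te_families is 0")
    rng = config.rng(1)
    chroms = list(config.chrom_lengths)

    genes: list[GeneModel] = []
    tes: list[TEElement] = []
    cursors = {c: 2500 for c in chroms}

    # family definitions
    families = []
    for i in range(config.n_te_families):
        sf = NON_HELITRON_SUPERFAMILIES[i % len(NON_HELITRON_SUPERFAMILIES)]
        length = int(rng.integers(800, 3001))
        families.append((f"{sf}{i + 1:05d}", sf, length))

    n_elements = config.n_te_families * config.copies_per_family
    n_nested = (
        max(1, round(config.nested_te_fraction * n_elements))
        if config.nested_te_fraction > 0
        else 0
    )
    n_helitrons = max(1, round(config.helitron_fraction * n_elements))

    # interleave genes and TE copies along the chromosomes
    placements: list[tuple[str, object]] = [("gene", i) for i in range(config.n_genes)]
    for fam_i, (fam, sf, length) in enumerate(families):
        for copy_i in range(config.copies_per_family):
            placements.append(("te", (fam_i, copy_i)))
    for h in range(n_helitrons):
        placements.append(("helitron", h))
    rng.shuffle(placements)

    def place(length: int) -> tuple[str, int]:
        gap = int(rng.integers(500, 2001))
        # fill the emptiest chromosome first so requested feature counts
        # are exact or the failure is loud
        for chrom in sorted(chroms, key=lambda c: (cursors[c], c)):
            start = cursors[chrom] + gap
            if start + length + 2500 <= config.chrom_length_bp:
                cursors[chrom] = start + length
                return chrom, start
        raise ValueError(
            "genome too small for the requested genes and TE elements; "
            "increase chrom_length_bp or n_chromosomes"
        )

    gc = lambda: float(np.clip(rng.normal(0.45, 0.05), 0.2, 0.8))
    for kind, payload in placements:
        if kind == "gene":
            glen = int(rng.integers(2000, 5001))
            chrom, start = place(glen)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(
                np.arange(200, glen - 200, 50), size=2 * (n_exons - 1), replace=False
            )) if n_exons > 1 else np.array([], dtype=int)
            edges = [0, *bounds.tolist(), glen]
            exons = tuple(
                (start + edges[2 * k], start + edges[2 * k + 1])
                for k in range(n_exons)
            )
            exons = tuple((s, e) for s, e in exons if e - s >= FRAGMENT_BP + 20)
            if not exons:
                exons = ((start, start + glen),)
            gid = f"gene{len(genes) + 1:04d}"
            genes.append(GeneModel(gid, chrom, start, start + glen, strand, exons))
        elif kind == "te":
            fam_i, copy_i = payload
            fam, sf, length = families[fam_i]
            eid = f"{fam}_e{copy_i + 1}"
            ltr = (
                float(rng.uniform(0.80, 0.995))
                if sf in LTR_SUPERFAMILIES
                else None
            )
            chrom, start = place(length)
            tes.append(
                TEElement(eid, fam, sf, chrom, start, start + length,
                          ltr_similarity=ltr, gc_content=gc())
            )
        else:  # helitron
            length = int(rng.integers(500, 2000))
            chrom, start = place(length)
            fam = f"DHH{payload + 1:05d}"
            tes.append(
                TEElement(f"{fam}_e1", fam, "DHH", chrom, start, start + length,
                          gc_content=gc())
            )

    # nested insertions: relocate the last-placed copies of the largest
    # elements' families strictly inside a host element of another family
    hosts = [t for t in tes if not t.is_helitron and t.length >= 1200]
    movable = [
        t for t in tes
        if not t.is_helitron and t.length <= 600 or t.element_id.endswith(f"_e{config.copies_per_family}")
    ]
    nested_done = 0
    for host in hosts:
        if nested_done >= n_nested:
            break
        candidates = [
            t for t in movable
            if t.family != host.family and t.length < host.length - 200
            and not t.is_helitron
        ]
        if not candidates:
            continue
        guest = candidates[0]
        movable.remove(guest)
        tes.remove(guest)
        inner_len = min(guest.length, host.length - 200)
        inner_start = host.start + 100
        tes.append(
            TEElement(guest.element_id, guest.family, guest.superfamily,
                      host.chrom, inner_start, inner_start + inner_len,
                      ltr_similarity=guest.ltr_similarity,
                      gc_content=guest.gc_content)
        )
        nested_done += 1

    # one TE overlapping a gene exon
    if genes and tes:
        target_gene = genes[0]
        exon_s, exon_e = target_gene.exons[0]
        candidates = [t for t in tes if not t.is_helitron and t.length >= 400]
        guest = candidates[-1]
        tes.remove(guest)
        new_start = max(0, exon_s - guest.length // 2)
        tes.append(
            TEElement(guest.element_id, guest.family, guest.superfamily,
                      target_gene.chrom, new_start, new_start + guest.length,
                      ltr_similarity=guest.ltr_similarity,
                      gc_content=guest.gc_content)
        )

    genes.sort(key=lambda g: (g.chrom, g.start))
    tes.sort(key=lambda t: (t.chrom, t.start, t.element_id))

    truth = TruthSet()
    truth.dmrs = list(
        config.dmr_spec
        if config.dmr_spec is not None
        else _default_dmr_spec(config, rng)
    )
    truth.islands = list(
        config.island_spec
        if config.island_spec is not None
        else _default_island_spec(config, rng)
    )
    for chrom, tile, context, la, lb in truth.dmrs:
        _check_level(la)
        _check_level(lb)
        if tile >= config.chrom_lengths[chrom]:
            raise ValueError(f"planted DMR tile {chrom}:{tile} outside genome")
    for chrom, tile, level in truth.islands:
        _check_level(level)
        if tile >= config.chrom_lengths[chrom]:
            raise ValueError(f"planted island tile {chrom}:{tile} outside genome")

    # planted DE: a quarter of families and a tenth of genes, alternating up/down
    fam_names = sorted({t.family for t in tes if not t.is_helitron})
    de_fams = fam_names[:: max(1, len(fam_names) // max(1, len(fam_names) // 4))][
        : max(1, len(fam_names) // 4)
    ]
    de_genes = [g.gene_id for g in genes][: max(1, len(genes) // 10)]
    for i, feat in enumerate([*de_genes, *de_fams]):
        direction = "up" if i % 2 == 0 else "down"
        lfc = config.planted_log2fc if direction == "up" else -config.planted_log2fc
        truth.de_features[feat] = (direction, lfc)
    return genes, tes, truth


def _check_level(level: float) -> None:
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level outside [0, 1]: {level}")


def _default_dmr_spec(config, rng) -> list[tuple[str, int, str, float, float]]:
    chroms = list(config.chrom_lengths)
    n_tiles = config.chrom_length_bp // 100
    spec = []
    picks = rng.choice(n_tiles - 2, size=6, replace=False)
    contexts = ["CG", "CG", "CHG", "CHG", "CHH", "CHH"]
    for i, (tile_i, ctx) in enumerate(zip(picks, contexts)):
        chrom = chroms[i % len(chroms)]
        if ctx == "CHH":
            # both sides well clear of the <5% / >25% gates at the default
            # coverage, so planted truth satisfies the gates it is meant to
            # exercise rather than riding the binomial noise floor
            la, lb = 0.005, 0.45
        else:
            la, lb = 0.85, 0.10
        spec.append((chrom, int(tile_i) * 100, ctx, la, lb))
    return spec


def _default_island_spec(config, rng) -> list[tuple[str, int, float]]:
    chroms = list(config.chrom_lengths)
    n_tiles = config.chrom_length_bp // 100
    picks = rng.choice(n_tiles - 2, size=4, replace=False)
    return [
        (chroms[i % len(chroms)], int(t) * 100, 0.40) for i, t in enumerate(picks)
    ]


# ---------------------------------------------------------------------------
# Alignments


def simulate_alignments(
    genes: Sequence[GeneModel],
    resolved: ResolvedAnnotation,
    config: SyntheticConfig,
    ambiguous_fraction: float = 0.02,
    improper_fraction: float = 0.02,
    intergenic_fraction: float = 0.01,
    te_fraction: float = 0.25,
    unique_te_fraction: float = 0.30,
) -> tuple[list[AlignmentRecord], dict[str, tuple[str, str, str]]]:
    """Simulate one library of read-pair fragments with truth labels.

    Gene reads land wholly inside one exon with a single hit. TE family
    reads come in two flavors: body reads from the sequence every copy
    shares, reported with one hit per copy (inside a resolved interval the
    copy still owns; fully-masked copies contribute no hit), and — a
    ``unique_te_fraction`` of them — junction/flank-context reads that map
    uniquely to one element, drawn by per-family element weights so one
    member often dominates. A small fraction of reads is made deliberately
    ambiguous (hits in two families), improperly paired, or intergenic.
    Returns (records, labels) with labels mapping
    read_id → (kind, family_or_gene, element_id_or_empty); kinds are
    gene / te / ambiguous / improper / intergenic.
    """
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = config.rng(2)

    exon_pool = []
    for g in genes:
        for s, e in g.exons:
            if e - s >= FRAGMENT_BP:
                exon_pool.append((g.gene_id, g.chrom, s, e))
    te_intervals: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, s, e, owner, kind in resolved.intervals:
        if kind == "te_element" and e - s >= FRAGMENT_BP:
            te_intervals.setdefault(owner, []).append((chrom, s, e))
    fam_elements: dict[str, list[str]] = {}
    for eid, te in resolved.element_index.items():
        if eid in te_intervals:
            fam_elements.setdefault(te.family, []).append(eid)
    for elems in fam_elements.values():
        elems.sort()
    fam_names = sorted(fam_elements)
    if not fam_names or not exon_pool:
        raise ValueError("annotation offers no place to simulate reads from")

    gene_w = rng.lognormal(0.0, 1.0, len(exon_pool))
    gene_w /= gene_w.sum()
    fam_w = rng.lognormal(0.0, 1.0, len(fam_names))
    fam_w /= fam_w.sum()
    # per-family element weights for unique reads; a sparse Dirichlet makes
    # one member dominate in many families (locus-specific expression)
    element_w = {
        fam: rng.dirichlet([0.3] * len(fam_elements[fam]))
        for fam in fam_names
    }

    # intergenic pool: per chromosome, positions not owned by anything
    owned: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, *_ in resolved.intervals:
        owned.setdefault(chrom, []).append((s, e))
    for g in genes:
        owned.setdefault(g.chrom, []).append((g.start, g.end))
    free: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_lengths.items():
        merged = []
        for s, e in sorted(owned.get(chrom, [])):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        prev = 0
        for s, e in merged:
            if s - prev >= FRAGMENT_BP:
                free.append((chrom, prev, s))
            prev = e
        if length - prev >= FRAGMENT_BP:
            free.append((chrom, prev, length))

    records: list[AlignmentRecord] = []
    labels: dict[str, tuple[str, str, str]] = {}
    u = rng.random(config.read_depth)
    thresholds = np.cumsum(
        [ambiguous_fraction, improper_fraction, intergenic_fraction, te_fraction]
    )
    for i in range(config.read_depth):
        rid = f"read{i + 1:07d}"
        x = u[i]
        if x < thresholds[0] and len(fam_names) >= 2:
            fa, fb = rng.choice(len(fam_names), size=2, replace=False)
            hits = tuple(
                _sample_hit(te_intervals[rng.choice(fam_elements[fam_names[f]])], rng)
                for f in (fa, fb)
            )
            records.append(AlignmentRecord(rid, hits, True))
            labels[rid] = ("ambiguous", "", "")
        elif x < thresholds[1]:
            gi = rng.choice(len(exon_pool), p=gene_w)
            gid, chrom, s, e = exon_pool[gi]
            hits = (_sample_hit([(chrom, s, e)], rng),)
            records.append(AlignmentRecord(rid, hits, False))
            labels[rid] = ("improper", gid, "")
        elif x < thresholds[2] and free:
            chrom, s, e = free[rng.choice(len(free))]
            hits = (_sample_hit([(chrom, s, e)], rng),)
            records.append(AlignmentRecord(rid, hits, True))
            labels[rid] = ("intergenic", "", "")
        elif x < thresholds[3]:
            fam = fam_names[rng.choice(len(fam_names), p=fam_w)]
            if rng.random() < unique_te_fraction:
                elems = fam_elements[fam]
                eid = elems[rng.choice(len(elems), p=element_w[fam])]
                hits = (_sample_hit(te_intervals[eid], rng),)
                records.append(AlignmentRecord(rid, hits, True))
                labels[rid] = ("te", fam, eid)
            else:
                hits = tuple(
                    _sample_hit(te_intervals[eid], rng)
                    for eid in sorted(fam_elements[fam])
                )[:20]
                records.append(AlignmentRecord(rid, hits, True))
                labels[rid] = ("te", fam, "")
        else:
            gi = rng.choice(len(exon_pool), p=gene_w)
            gid, chrom, s, e = exon_pool[gi]
            hits = (_sample_hit([(chrom, s, e)], rng),)
            records.append(AlignmentRecord(rid, hits, True))
            labels[rid] = ("gene", gid, "")
    return records, labels


def _sample_hit(intervals: list[tuple[str, int, int]], rng) -> tuple[str, int, int, str]:
    chrom, s, e = intervals[int(rng.integers(len(intervals)))]
    start = int(rng.integers(s, e - FRAGMENT_BP + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return (chrom, start, start + FRAGMENT_BP, strand)


def write_sam(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write records as paired-end SAM, one mate pair per reported hit."""
    import pysam

    chroms = sorted(chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            nh = len(rec.hits)
            for hi, (chrom, start, end, strand) in enumerate(rec.hits):
                for mate in (1, 2):
                    a = pysam.AlignedSegment(header)
                    a.query_name = rec.read_id
                    a.reference_id = tid[chrom]
                    first = (mate == 1) == (strand == "+")
                    a.reference_start = start if first else end - MATE_BP
                    a.cigarstring = f"{MATE_BP}M"
                    flag = 0x1 | (0x40 if mate == 1 else 0x80)
                    if rec.properly_paired:
                        flag |= 0x2
                    if (mate == 2) == (strand == "+"):
                        flag |= 0x10
                    else:
                        flag |= 0x20
                    if hi > 0:
                        flag |= 0x100
                    a.flag = flag
                    a.next_reference_id = tid[chrom]
                    a.next_reference_start = end - MATE_BP if first else start
                    a.template_length = (end - start) if first else -(end - start)
                    a.mapping_quality = 60 if nh == 1 else 1
                    a.set_tag("NH", nh)
                    a.set_tag("HI", hi)
                    out.write(a)


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    features: Sequence[str],
    truth: TruthSet,
    config: SyntheticConfig,
    contrasts: Sequence[str] = ("mutA", "mutB"),
    pathway: str = "CMT",
    base_mean_log: float = np.log(300.0),
    base_mean_sigma: float = 0.5,
):
    """NB count table for mutant/control libraries of each contrast.

    Planted DE features (from the truth set) have their mutant-group mean
    multiplied by 2^log2fc in every contrast; planted baselines are kept at
    ≥100 so the effect is identifiable at the simulated depth. Returns
    (counts DataFrame, list of diffexpr.Contrast).
    """
    from .diffexpr import Contrast

    rng = config.rng(3)
    alpha = config.dispersion
    features = list(features)
    base = rng.lognormal(base_mean_log, base_mean_sigma, len(features))
    planted = np.array([f in truth.de_features for f in features])
    base = np.where(planted, np.maximum(base, 100.0), base)
    lfc = np.array(
        [truth.de_features.get(f, ("ns", 0.0))[1] for f in features], dtype=float
    )

    def draw(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    cols = {}
    contrast_objs = []
    n = config.n_libraries_per_genotype
    for cname in contrasts:
        mut_libs, ctl_libs = [], []
        for r in range(n):
            lib = f"{cname}_mut_{r + 1}"
            cols[lib] = draw(base * np.exp2(lfc))
            mut_libs.append(lib)
        for r in range(n):
            lib = f"{cname}_ctl_{r + 1}"
            cols[lib] = draw(base)
            ctl_libs.append(lib)
        contrast_objs.append(
            Contrast(cname, tuple(mut_libs), tuple(ctl_libs), pathway)
        )
    counts = pd.DataFrame(cols, index=features)
    return counts, contrast_objs


# ---------------------------------------------------------------------------
# Methylation


def simulate_methylation(
    truth: TruthSet,
    config: SyntheticConfig,
    genotypes: Sequence[str] = ("A", "B"),
) -> dict[str, pd.DataFrame]:
    """Per-cytosine methylation call tables for each genotype.

    Cytosine positions and contexts are a genome property shared by all
    genotypes; coverage (Poisson around ``coverage_mean``, min 1) and
    methylated-read counts (binomial at the tile's level) are per genotype.
    Background levels are CG 0.80 / CHG 0.65 / CHH 0.02. Planted DMR tiles
    use level_A in the first genotype and level_B in every other; planted
    island tiles put the specified CHH level in all genotypes. Planted tiles
    are given enough sites to pass the site-count gate.
    """
    for chrom, tile, ctx, la, lb in truth.dmrs:
        _check_level(la)
        _check_level(lb)
        if tile >= config.chrom_lengths[chrom]:
            raise ValueError(f"planted DMR tile {chrom}:{tile} outside genome")
    for chrom, tile, lvl in truth.islands:
        _check_level(lvl)
        if tile >= config.chrom_lengths[chrom]:
            raise ValueError(f"planted island tile {chrom}:{tile} outside genome")
    rng_sites = config.rng(4)
    dmr_by_tile = {(c, t, ctx): (la, lb) for c, t, ctx, la, lb in truth.dmrs}
    island_by_tile = {(c, t): lvl for c, t, lvl in truth.islands}

    # genome-wide site layout
    site_chrom, site_pos, site_ctx = [], [], []
    for chrom, length in sorted(config.chrom_lengths.items()):
        for tile in range(0, length, 100):
            tile_len = min(100, length - tile)
            for ctx, lam in SITES_PER_TILE.items():
                n_sites = int(rng_sites.poisson(lam))
                if (chrom, tile, ctx) in dmr_by_tile or (
                    ctx == "CHH" and (chrom, tile) in island_by_tile
                ):
                    n_sites = max(n_sites, 8)
                n_sites = min(n_sites, tile_len)
                if n_sites == 0:
                    continue
                pos = rng_sites.choice(tile_len, size=n_sites, replace=False) + tile
                site_chrom.extend([chrom] * n_sites)
                site_pos.extend(pos.tolist())
                site_ctx.extend([ctx] * n_sites)

    sites = pd.DataFrame(
        {
            "chrom": site_chrom,
            "pos": np.asarray(site_pos, dtype=int),
            "strand": rng_sites.choice(["+", "-"], size=len(site_pos)),
            "context": site_ctx,
        }
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    tile_key = list(
        zip(sites["chrom"], (sites["pos"] // 100) * 100, sites["context"])
    )

    out = {}
    for gi, genotype in enumerate(genotypes):
        rng = config.rng(100 + gi)
        level = np.array([BACKGROUND_LEVELS[c] for c in sites["context"]])
        for i, (chrom, tile, ctx) in enumerate(tile_key):
            spec = dmr_by_tile.get((chrom, tile, ctx))
            if spec is not None:
                level[i] = spec[0] if gi == 0 else spec[1]
            elif ctx == "CHH" and (chrom, tile) in island_by_tile:
                level[i] = island_by_tile[(chrom, tile)]
        total = np.maximum(rng.poisson(config.coverage_mean, len(sites)), 1)
        mc = rng.binomial(total, level)
        table = sites.copy()
        table["mc_reads"] = mc
        table["total_reads"] = total
        out[genotype] = table
    return out


# ---------------------------------------------------------------------------
# Epiallele panel


def simulate_epiallele_panel(
    config: SyntheticConfig,
    n_genotypes: int = 10,
    n_epiallele: int = 50,
    n_null: int = 200,
    expressed_mean: float = 100.0,
    silenced_mean: float = 1.0,
):
    """Methylation/expression panel with planted epiallele genes.

    Epiallele genes are bimodal across the panel: in "methylated" genotypes
    the DMR sits near 0.9 methylation and the gene is silenced; in
    unmethylated genotypes the DMR is near 0.05 and the gene expresses at
    ``expressed_mean`` (NB noise at the configured dispersion). Null genes
    have methylation and expression drawn independently. Returns
    (methylation DataFrame, expression DataFrame, truth dict gene→bool).
    """
    rng = config.rng(5)
    alpha = config.dispersion
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    meth_rows, expr_rows, truth = {}, {}, {}

    def nb(mu, size):
        return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size)

    for i in range(n_epiallele):
        gid = f"epi{i + 1:04d}"
        while True:
            methylated = rng.random(n_genotypes) < 0.5
            if 2 <= methylated.sum() <= n_genotypes - 2:
                break
        meth = np.where(
            methylated,
            np.clip(rng.normal(0.90, 0.05, n_genotypes), 0, 1),
            np.clip(rng.normal(0.05, 0.03, n_genotypes), 0, 1),
        )
        expr = np.where(
            methylated,
            nb(silenced_mean, n_genotypes),
            nb(expressed_mean, n_genotypes),
        ).astype(float)
        meth_rows[gid], expr_rows[gid], truth[gid] = meth, expr, True
    for i in range(n_null):
        gid = f"null{i + 1:04d}"
        meth_rows[gid] = np.clip(rng.normal(0.5, 0.15, n_genotypes), 0, 1)
        expr_rows[gid] = nb(expressed_mean / 2, n_genotypes).astype(float)
        truth[gid] = False
    meth = pd.DataFrame(meth_rows, index=genotypes).T
    expr = pd.DataFrame(expr_rows, index=genotypes).T
    return meth, expr, truth
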