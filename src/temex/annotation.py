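"""Disjoint, exon-masked TE annotation construction.

Maize TE annotations are heavily nested: younger insertions interrupt older
copies, and helitrons capture fragments of everything. Before any read
counting, the element annotation is flattened so that every genomic base is
owned by exactly one TE element, helitrons are dropped, and exonic bases are
subtracted so gene transcription is never mistaken for TE expression. Gene
exons are then merged in as first-class owners, giving a single disjoint
interval set that all downstream counting queries.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Superfamily codes of the maize TE taxonomy. R* = class I (retrotransposons,
# copy-and-paste via RNA), D* = class II (DNA transposons, cut-and-paste).
SUPERFAMILY_CLASS = {
    "RST": "I",   # SINE
    "RIT": "I",   # LINE
    "RIL": "I",   # LINE L1-like
    "RLX": "I",   # LTR unclassified
    "RLG": "I",   # LTR Gypsy
    "RLC": "I",   # LTR Copia
    "DTX": "II",  # TIR unclassified
    "DTT": "II",  # TIR Tc1/Mariner
    "DTH": "II",  # TIR PIF/Harbinger
    "DTC": "II",  # CACTA
    "DTM": "II",  # TIR Mutator
    "DTA": "II",  # TIR hAT
    "DHH": "II",  # Helitron
}

HELITRON_SUPERFAMILIES = frozenset({"DHH"})

LTR_SUPERFAMILIES = frozenset({"RLX", "RLG", "RLC"})


def te_class_for_superfamily(code: str) -> str:
    """Class I (retro) / II (DNA) from the three-letter superfamily code."""
    try:
        return SUPERFAMILY_CLASS[code]
    except KeyError:
        # Fall back on the leading letter convention for codes outside the
        # curated table (R = retro, D = DNA).
        if code.startswith("R"):
            return "I"
        if code.startswith("D"):
            return "II"
        raise ValueError(f"unknown TE superfamily code: {code!r}") from None


@dataclass(frozen=True)
class TEElement:
    """A single annotated TE copy at one genomic location."""

    element_id: str
    family: str
    superfamily: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    ltr_similarity: float | None = None
    gc_content: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"TE {self.element_id}: start {self.start} >= end {self.end}"
            )
        if not self.family:
            raise ValueError(f"TE {self.element_id}: empty family")

    @property
    def te_class(self) -> str:
        return te_class_for_superfamily(self.superfamily)

    @property
    def is_helitron(self) -> bool:
        return self.superfamily in HELITRON_SUPERFAMILIES

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its exon intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")

    @property
    def tss(self) -> int:
        """Transcription start: start on +, end on − (half-open convention)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class ResolvedAnnotation:
    """Disjoint owned intervals plus the element→family hierarchy index.

    ``intervals`` rows are (chrom, start, end, owner_id, owner_kind) with
    owner_kind one of ``gene_exon`` / ``te_element``. ``element_index`` keeps
    every non-helitron element (including fully masked ones, which own zero
    bases) so family-size statistics are unaffected by masking.
    """

    intervals: list[tuple[str, int, int, str, str]]
    element_index: dict[str, TEElement] = field(default_factory=dict)
    gene_index: dict[str, GeneModel] = field(default_factory=dict)
    fully_masked: set[str] = field(default_factory=set)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False)

    def family_of(self, element_id: str) -> str:
        return self.element_index[element_id].family

    @property
    def families(self) -> list[str]:
        return sorted({te.family for te in self.element_index.values()})

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom_, s, e, owner, kind in self.intervals:
                trees.setdefault(chrom_, IntervalTree()).addi(s, e, (owner, kind))
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        """Owners of intervals overlapping [start, end) by ≥1 bp."""
        return [iv.data for iv in self._tree(chrom).overlap(start, end)]

    def to_bed(self, path: str) -> None:
        """BED6 of owned intervals; name = owner id, score column = kind."""
        rows = sorted(self.intervals)
        with open(path, "w") as fh:
            for chrom, s, e, owner, kind in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{owner}\t0\t.\t{kind}\n")

    def family_map_table(self):
        """Element→family→superfamily→class map as a DataFrame."""
        import pandas as pd

        rows = [
            {
                "element_id": te.element_id,
                "family": te.family,
                "superfamily": te.superfamily,
                "te_class": te.te_class,
                "fully_masked": te.element_id in self.fully_masked,
            }
            for te in self.element_index.values()
        ]
        return pd.DataFrame(rows).sort_values("element_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GFF3 I/O


def load_annotations(
    gene_gff3_path: str, te_annotation_path: str
) -> tuple[list[GeneModel], list[TEElement]]:
    """Read gene and TE GFF3 files into internal 0-based models.

    Gene files must carry ``gene`` features with child ``exon`` features
    (Parent attribute). TE files carry one feature per element with
    ``ID``, ``family`` and ``superfamily`` attributes; ``ltr_similarity``
    and ``gc_content`` are optional.
    """
    genes = _load_gene_gff3(gene_gff3_path)
    tes = _load_te_gff3(te_annotation_path)
    return genes, tes


def _gff3_features(path: str):
    import gffutils.iterators

    yield from gffutils.iterators.DataIterator(path)


def _attr(feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def _load_gene_gff3(path: str) -> list[GeneModel]:
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for f in _gff3_features(path):
        s, e = f.start - 1, f.end  # GFF3 1-based inclusive → half-open
        if f.featuretype == "gene":
            gid = _attr(f, "ID")
            if not gid:
                raise ValueError(f"gene record without ID in {path}")
            spans[gid] = (f.seqid, s, e, f.strand)
        elif f.featuretype == "exon":
            parent = _attr(f, "Parent")
            if not parent:
                raise ValueError(f"exon record without Parent in {path}")
            exons.setdefault(parent, []).append((s, e))
    genes = []
    for gid, (chrom, s, e, strand) in spans.items():
        ex = tuple(sorted(exons.get(gid, [(s, e)])))
        genes.append(GeneModel(gid, chrom, s, e, strand, ex))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _load_te_gff3(path: str) -> list[TEElement]:
    tes = []
    for f in _gff3_features(path):
        if f.featuretype == "exon" or f.featuretype == "gene":
            continue
        eid = _attr(f, "ID")
        if not eid:
            raise ValueError(f"TE record without ID in {path}")
        family = _attr(f, "family")
        if not family:
            raise ValueError(f"TE record {eid} missing family attribute")
        superfam = _attr(f, "superfamily")
        if not superfam:
            raise ValueError(f"TE record {eid} missing superfamily attribute")
        ltr = _attr(f, "ltr_similarity")
        gc = _attr(f, "gc_content")
        tes.append(
            TEElement(
                element_id=eid,
                family=family,
                superfamily=superfam,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                ltr_similarity=float(ltr) if ltr is not None else None,
                gc_content=float(gc) if gc is not None else None,
            )
        )
    tes.sort(key=lambda t: (t.chrom, t.start, t.element_id))
    return tes


def write_gene_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_te_gff3(tes: Sequence[TEElement], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes:
            attrs = (
                f"ID={t.element_id};family={t.family};superfamily={t.superfamily}"
            )
            if t.ltr_similarity is not None:
                attrs += f";ltr_similarity={t.ltr_similarity:.4f}"
            if t.gc_content is not None:
                attrs += f";gc_content={t.gc_content:.4f}"
            fh.write(
                f"{t.chrom}\tsynthetic\ttransposable_element\t{t.start + 1}\t"
                f"{t.end}\t.\t.\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Resolution


def remove_helitrons(tes: Iterable[TEElement]) -> list[TEElement]:
    """Drop helitron elements; everything else passes through unchanged."""
    tes = list(tes)
    kept = [t for t in tes if not t.is_helitron]
    if tes and not kept:
        logger.warning("all %d TE elements were helitrons; nothing retained", len(tes))
    return kept


def _subtract(segments: list[tuple[int, int]], cut: tuple[int, int]) -> list[tuple[int, int]]:
    """Interval-list minus one interval."""
    cs, ce = cut
    out = []
    for s, e in segments:
        if ce <= s or cs >= e:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs))
        if ce < e:
            out.append((ce, e))
    return out


def resolve_overlaps(tes: Sequence[TEElement]) -> ResolvedAnnotation:
    """Assign every TE-covered base to exactly one element.

    Contested bases go to the shorter element (nested insertions are younger
    and interrupt the older copy they sit in); ties break lexicographically
    by element id, so the outcome is deterministic. The union of output
    bases equals the union of input bases.
    """
    if any(t.is_helitron for t in tes):
        raise ValueError("resolve_overlaps requires helitrons removed first")
    intervals: list[tuple[str, int, int, str, str]] = []
    fully_masked: set[str] = set()
    by_chrom: dict[str, list[TEElement]] = {}
    for t in tes:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, elements in by_chrom.items():
        claimed = IntervalTree()
        # shortest first; nested (younger) elements claim their bases whole
        for t in sorted(elements, key=lambda x: (x.length, x.element_id)):
            segments = [(t.start, t.end)]
            for iv in claimed.overlap(t.start, t.end):
                segments = _subtract(segments, (iv.begin, iv.end))
            if not segments:
                fully_masked.add(t.element_id)
            for s, e in segments:
                intervals.append((chrom, s, e, t.element_id, "te_element"))
                claimed.addi(s, e)
    resolved = ResolvedAnnotation(
        intervals=sorted(intervals),
        element_index={t.element_id: t for t in tes},
        fully_masked=fully_masked,
    )
    return resolved


def mask_exons(
    resolved_te: ResolvedAnnotation, genes: Sequence[GeneModel]
) -> ResolvedAnnotation:
    """Subtract exon bases from TE ownership and add exons as gene owners.

    Elements whose every base is removed stay in the element index, flagged
    fully masked, so family sizes are preserved.
    """
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for s, e in g.exons:
            exon_by_chrom.setdefault(g.chrom, []).append((s, e))
    exon_trees = {
        chrom: IntervalTree.from_tuples(ivs) for chrom, ivs in exon_by_chrom.items()
    }

    intervals: list[tuple[str, int, int, str, str]] = []
    surviving: set[str] = set()
    for chrom, s, e, owner, kind in resolved_te.intervals:
        tree = exon_trees.get(chrom)
        segments = [(s, e)]
        if tree is not None:
            for iv in tree.overlap(s, e):
                segments = _subtract(segments, (iv.begin, iv.end))
        for ss, ee in segments:
            intervals.append((chrom, ss, ee, owner, kind))
            surviving.add(owner)
    fully_masked = set(resolved_te.fully_masked)
    fully_masked |= {
        eid for eid in resolved_te.element_index if eid not in surviving
    }
    for g in genes:
        for s, e in g.exons:
            intervals.append((g.chrom, s, e, g.gene_id, "gene_exon"))
    return ResolvedAnnotation(
        intervals=sorted(intervals),
        element_index=dict(resolved_te.element_index),
        gene_index={g.gene_id: g for g in genes},
        fully_masked=fully_masked,
    )


def build_resolved_annotation(
    genes: Sequence[GeneModel], tes: Sequence[TEElement]
) -> ResolvedAnnotation:
    """remove_helitrons → resolve_overlaps → mask_exons, in one call."""
    return mask_exons(resolve_overlaps(remove_helitrons(tes)), genes)
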