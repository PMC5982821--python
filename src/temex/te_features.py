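"""Characterization of TE families with altered expression.

Families are profiled by size class (single, small 2–9, medium 10–99,
large ≥100 members), mean LTR similarity where the order applies (the
percent identity between an element's two long terminal repeats decays
with insertion age, so similar LTRs mark young elements), mean GC content,
and distance to the nearest gene. A Welch t-test compares a DE family
subset against the genome-wide distribution of any of these attributes.

For small families (<10 elements) where at least half of the reads mapped
uniquely, per-element unique read counts distinguish locus-specific
reactivation (one element dominating the unique reads) from coordinate
reactivation of several members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, TEElement, LTR_SUPERFAMILIES

SIZE_CLASS_BOUNDS = ((1, 1, "single"), (2, 9, "small"), (10, 99, "medium"))
TESTABLE_MAX_MEMBERS = 10      # strictly fewer members than this
TESTABLE_MIN_UNIQUE_FRACTION = 0.50
DOMINANCE_THRESHOLD = 0.90     # unique-read share calling one element dominant
FEATURE_TEST_P = 0.01


def size_class(n_members: int) -> str:
    """single / small (2–9) / medium (10–99) / large (≥100)."""
    if n_members < 1:
        raise ValueError("family must have at least one member")
    for lo, hi, name in SIZE_CLASS_BOUNDS:
        if lo <= n_members <= hi:
            return name
    return "large"


def _nearest_gene_distance(
    te: TEElement, genes_by_chrom: Mapping[str, list[GeneModel]]
) -> float:
    best = np.inf
    for g in genes_by_chrom.get(te.chrom, ()):
        if g.end <= te.start:
            d = te.start - g.end
        elif g.start >= te.end:
            d = g.start - te.end
        else:
            d = 0
        best = min(best, d)
    return best


@dataclass
class TEFamilySummary:
    family: str
    superfamily: str
    te_class: str
    n_members: int
    size_class: str
    mean_ltr_similarity: float | None
    mean_gc: float | None
    mean_distance_to_gene_bp: float | None
    de_status: dict[str, str]


def family_summary(
    tes: Sequence[TEElement],
    genes: Sequence[GeneModel],
    de_sets: Mapping[str, Mapping[str, set[str]]] | None = None,
) -> list[TEFamilySummary]:
    """Per-family attribute summary over the element annotation.

    ``de_sets`` is the consistent-DE structure {pathway: {"up": set,
    "down": set}} over family names; absent families get status "ns".
    """
    de_sets = de_sets or {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    by_family: dict[str, list[TEElement]] = {}
    for t in tes:
        by_family.setdefault(t.family, []).append(t)
    summaries = []
    for family in sorted(by_family):
        members = by_family[family]
        ltrs = [
            t.ltr_similarity
            for t in members
            if t.ltr_similarity is not None and t.superfamily in LTR_SUPERFAMILIES
        ]
        gcs = [t.gc_content for t in members if t.gc_content is not None]
        dists = [
            d
            for d in (_nearest_gene_distance(t, genes_by_chrom) for t in members)
            if np.isfinite(d)
        ]
        status = {}
        for pathway, sets in de_sets.items():
            if family in sets.get("up", ()):
                status[pathway] = "up"
            elif family in sets.get("down", ()):
                status[pathway] = "down"
            else:
                status[pathway] = "ns"
        summaries.append(
            TEFamilySummary(
                family=family,
                superfamily=members[0].superfamily,
                te_class=members[0].te_class,
                n_members=len(members),
                size_class=size_class(len(members)),
                mean_ltr_similarity=float(np.mean(ltrs)) if ltrs else None,
                mean_gc=float(np.mean(gcs)) if gcs else None,
                mean_distance_to_gene_bp=float(np.mean(dists)) if dists else None,
                de_status=status,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[TEFamilySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "family": s.family,
            "superfamily": s.superfamily,
            "te_class": s.te_class,
            "n_members": s.n_members,
            "size_class": s.size_class,
            "mean_ltr_similarity": s.mean_ltr_similarity,
            "mean_gc": s.mean_gc,
            "mean_distance_to_gene_bp": s.mean_distance_to_gene_bp,
        }
        for pathway, status in s.de_status.items():
            row[f"de_{pathway}"] = status
        rows.append(row)
    return pd.DataFrame(rows)


def compare_feature_to_genomewide(
    values_subset: Sequence[float],
    values_all: Sequence[float],
    p_cutoff: float = FEATURE_TEST_P,
) -> tuple[float, float, bool]:
    """Welch t-test of a family subset attribute against the genome-wide set.

    Returns (t, p, significant). The t statistic is positive when the subset
    mean exceeds the genome-wide mean.
    """
    a = np.asarray(values_subset, dtype=float)
    b = np.asarray(values_all, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < p_cutoff)


@dataclass
class FamilyExpressionPattern:
    family: str
    testable: bool
    pattern: str  # locus_specific / coordinate / untestable
    per_element_unique_fraction: dict[str, float]
    unique_fraction_of_total: float


def classify_family_pattern(
    family: str,
    element_unique_counts: Mapping[str, int],
    family_total_reads: int,
    n_members: int | None = None,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> FamilyExpressionPattern:
    """Locus-specific vs coordinate expression from unique-read shares.

    A family is testable when it has fewer than 10 members and at least 50%
    of its reads were uniquely assigned; it is locus_specific when a single
    element holds at least ``dominance_threshold`` of the unique reads,
    coordinate otherwise.
    """
    n_members = n_members if n_members is not None else len(element_unique_counts)
    unique_total = sum(element_unique_counts.values())
    unique_fraction = unique_total / family_total_reads if family_total_reads else 0.0
    testable = (
        n_members < TESTABLE_MAX_MEMBERS
        and family_total_reads > 0
        and unique_fraction >= TESTABLE_MIN_UNIQUE_FRACTION
    )
    fractions: dict[str, float] = {}
    if testable and unique_total > 0:
        fractions = {
            eid: c / unique_total for eid, c in sorted(element_unique_counts.items())
        }
        top = max(fractions.values())
        pattern = "locus_specific" if top >= dominance_threshold else "coordinate"
    else:
        testable = testable and unique_total > 0
        pattern = "untestable"
    return FamilyExpressionPattern(
        family=family,
        testable=testable,
        pattern=pattern,
        per_element_unique_fraction=fractions,
        unique_fraction_of_total=unique_fraction,
    )


def classify_all_families(
    element_unique: Mapping[str, int],
    family_totals: Mapping[str, int],
    element_family: Mapping[str, str],
    members_per_family: Mapping[str, int],
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> list[FamilyExpressionPattern]:
    by_family: dict[str, dict[str, int]] = {f: {} for f in family_totals}
    for eid, count in element_unique.items():
        fam = element_family[eid]
        if fam in by_family:
            by_family[fam][eid] = count
    return [
        classify_family_pattern(
            fam,
            by_family.get(fam, {}),
            family_totals[fam],
            n_members=members_per_family.get(fam),
            dominance_threshold=dominance_threshold,
        )
        for fam in sorted(family_totals)
    ]
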