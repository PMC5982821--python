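"""Read filtering, hierarchical gene/TE assignment, counting and RPM."""

import numpy as np
import pandas as pd
import pytest

from temex.annotation import GeneModel, TEElement, build_resolved_annotation
from temex.quantify import (
    AlignmentRecord,
    AssignmentStatus,
    assign_te_reads,
    combine_libraries,
    count_genes,
    family_counts,
    filter_alignments,
    flag_expressed,
    load_sam,
    quantify_library,
    rpm_normalize,
    te_read_fraction,
)
from temex.synthetic import simulate_alignments, write_sam


def rec(rid, hits, paired=True):
    return AlignmentRecord(rid, tuple(hits), paired)


@pytest.fixture(scope="module")
def toy_resolved():
    """Two genes and two 2-copy families on one toy chromosome."""
    genes = [
        GeneModel("gA", "chr1", 1000, 2000, "+", ((1000, 1500), (1600, 2000))),
        GeneModel("gB", "chr1", 1950, 2600, "+", ((1950, 2600),)),
    ]
    tes = [
        TEElement("F1_e1", "F1", "RLG", "chr1", 3000, 3500),
        TEElement("F1_e2", "F1", "RLG", "chr1", 4000, 4500),
        TEElement("F2_e1", "F2", "DTA", "chr1", 5000, 5400),
        TEElement("F2_e2", "F2", "DTA", "chr1", 6000, 6400),
        TEElement("F3_e1", "F3", "RLC", "chr1", 7000, 7800),
    ]
    return genes, tes, build_resolved_annotation(genes, tes)


class TestFilter:
    def test_partition(self):
        records = [
            rec("u", [("chr1", 0, 150, "+")]),
            rec("m", [("chr1", 0, 150, "+"), ("chr1", 500, 650, "+")]),
            rec("bad", [("chr1", 0, 150, "+")], paired=False),
            rec("many", [("chr1", i * 200, i * 200 + 150, "+") for i in range(25)]),
        ]
        unique, multi = filter_alignments(records)
        assert [r.read_id for r in unique] == ["u"]
        assert [r.read_id for r in multi] == ["m"]

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError):
            AlignmentRecord("x", ())


class TestGeneCounting:
    def test_union_mode(self, toy_resolved):
        _, _, resolved = toy_resolved
        records = [
            rec("in_gA", [("chr1", 1100, 1250, "+")]),       # one gene
            rec("two_genes", [("chr1", 1900, 2050, "+")]),   # gA exon2 + gB
            rec("intergenic", [("chr1", 9000, 9150, "+")]),
            rec("intronic", [("chr1", 1510, 1590, "+")]),    # between exons
        ]
        counts = count_genes(records, resolved)
        assert counts == {"gA": 1, "gB": 0}


class TestTEAssignment:
    def test_statuses(self, toy_resolved):
        _, _, resolved = toy_resolved
        unique = [
            rec("el", [("chr1", 3100, 3250, "+")]),       # in F1_e1
            rec("gene", [("chr1", 1100, 1250, "+")]),
        ]
        multi = [
            rec("fam", [("chr1", 3100, 3250, "+"), ("chr1", 4100, 4250, "+")]),
            rec("ambig", [("chr1", 3100, 3250, "+"), ("chr1", 5100, 5250, "+")]),
            rec("conflict", [("chr1", 3100, 3250, "+"), ("chr1", 1100, 1250, "+")]),
            rec("nowhere", [("chr1", 9000, 9150, "+"), ("chr1", 9500, 9650, "+")]),
        ]
        by_id = {
            a.read_id: a for a in assign_te_reads(unique, multi, resolved)
        }
        assert by_id["el"].status is AssignmentStatus.TE_ELEMENT
        assert by_id["el"].target_id == "F1_e1"
        assert by_id["gene"].status is AssignmentStatus.GENE
        assert by_id["fam"].status is AssignmentStatus.TE_FAMILY_MULTI
        assert by_id["fam"].target_id == "F1"
        assert by_id["ambig"].status is AssignmentStatus.AMBIGUOUS_FAMILY
        assert by_id["conflict"].status is AssignmentStatus.GENE_TE_CONFLICT
        assert by_id["nowhere"].status is AssignmentStatus.UNASSIGNED

    def test_every_record_gets_exactly_one_status(self, small_config,
                                                  small_annotation,
                                                  small_resolved):
        genes, _, _ = small_annotation
        records, _ = simulate_alignments(genes, small_resolved, small_config)
        unique, multi = filter_alignments(records)
        assignments = assign_te_reads(unique, multi, small_resolved)
        assert len(assignments) == len(unique) + len(multi)
        assert len({a.read_id for a in assignments}) == len(assignments)

    def test_family_totals_combine_unique_and_multi(self, toy_resolved):
        _, _, resolved = toy_resolved
        unique = [rec(f"u{i}", [("chr1", 3100, 3250, "+")]) for i in range(10)]
        multi = [
            rec(f"m{i}", [("chr1", 3100, 3250, "+"), ("chr1", 4100, 4250, "+")])
            for i in range(5)
        ]
        counts = family_counts(
            assign_te_reads(unique, multi, resolved), resolved
        )
        assert counts.family_total["F1"] == 15
        assert counts.family_unique["F1"] == 10
        assert counts.family_multi["F1"] == 5
        assert counts.family_total["F2"] == 0  # zero row kept
        assert sum(
            c for e, c in counts.element_unique.items()
            if resolved.family_of(e) == "F1"
        ) == counts.family_unique["F1"]


class TestRPM:
    def test_rpm_value_and_column_sums(self):
        counts = pd.DataFrame({"lib1": [1000, 999_000]}, index=["fam", "gene"])
        rpm = rpm_normalize(counts)
        assert rpm.loc["fam", "lib1"] == pytest.approx(1000.0)
        assert rpm["lib1"].sum() == pytest.approx(1e6)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"l": [3, 7, 90]}, index=list("abc"))
        assert np.allclose(rpm_normalize(counts), rpm_normalize(counts * 2))

    def test_zero_denominator_errors(self):
        counts = pd.DataFrame({"l": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError):
            rpm_normalize(counts)

    @pytest.mark.parametrize(
        "rpms,expressed",
        [
            ((1.2, 1.5, 2.0, 0.3), True),
            ((1.2, 0.9, 0.8), False),
            ((1.0, 1.0, 1.0, 1.0), False),  # strict >
        ],
    )
    def test_flag_expressed(self, rpms, expressed):
        rpm = pd.DataFrame([rpms], index=["f"],
                           columns=[f"l{i}" for i in range(len(rpms))])
        assert ("f" in flag_expressed(rpm)) is expressed

    def test_te_read_fraction(self, toy_resolved):
        _, _, resolved = toy_resolved
        unique = [rec(f"u{i}", [("chr1", 3100, 3250, "+")]) for i in range(10)]
        genes = [rec(f"g{i}", [("chr1", 1100, 1250, "+")]) for i in range(90)]
        counts, _ = quantify_library(unique + genes, resolved)
        frac = te_read_fraction({"lib": counts})
        assert frac["lib"] == pytest.approx(0.10)


class TestSamRoundTrip:
    def test_records_survive_sam(self, tmp_path, small_config,
                                 small_annotation, small_resolved):
        genes, _, _ = small_annotation
        records, _ = simulate_alignments(genes, small_resolved, small_config)
        sam = tmp_path / "lib.sam"
        write_sam(records, small_config.chrom_lengths, str(sam))
        loaded = load_sam(str(sam))
        assert len(loaded) == len(records)
        orig = {r.read_id: r for r in records}
        for r in loaded:
            o = orig[r.read_id]
            assert r.properly_paired == o.properly_paired
            assert sorted((c, s, e) for c, s, e, _ in r.hits) == sorted(
                (c, s, e) for c, s, e, _ in o.hits
            )


def test_combined_counts_from_sam_match_in_memory(tmp_path, small_config,
                                                  small_annotation,
                                                  small_resolved):
    genes, _, _ = small_annotation
    records, _ = simulate_alignments(genes, small_resolved, small_config)
    counts_mem, _ = quantify_library(records, small_resolved)
    sam = tmp_path / "lib.sam"
    write_sam(records, small_config.chrom_lengths, str(sam))
    counts_sam, _ = quantify_library(load_sam(str(sam)), small_resolved)
    assert counts_mem.family_total == counts_sam.family_total
    assert counts_mem.gene_counts == counts_sam.gene_counts
    table = combine_libraries({"a": counts_mem, "b": counts_sam})
    assert (table["a"] == table["b"]).all()
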