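"""Metaprofiles, TSS methylation classes, proximity flags, enrichment and
epiallele correlation."""

import numpy as np
import pandas as pd
import pytest

from temex.annotation import GeneModel
from temex.association import (
    dmr_near_tss,
    enrichment_test,
    island_proximity,
    metaprofile,
    methylation_expression_correlation,
    tss_methylation_class,
)
from temex.methylation import DMRCatalogEntry, MCHHIsland


def uniform_tiles(chrom="chr1", n=400, context="CG", level=0.8, reads=50):
    return pd.DataFrame([
        {
            "chrom": chrom, "tile_start": i * 100, "context": context,
            "n_sites": 8, "mc_reads": level * reads, "total_reads": reads,
            "level": level, "mean_site_coverage": reads / 8,
        }
        for i in range(n)
    ])


def plus_gene(gid="g1", start=10_000, end=14_000):
    return GeneModel(gid, "chr1", start, end, "+", ((start, end),))


def minus_gene(gid="g2", start=20_000, end=24_000):
    return GeneModel(gid, "chr1", start, end, "-", ((start, end),))


class TestMetaprofile:
    def test_uniform_methylation_gives_flat_profile(self):
        tiles = uniform_tiles()
        genes = {"g1": plus_gene()}
        prof = metaprofile(genes, tiles, ["g1"], "CG")
        covered = prof[prof["n_genes"] > 0]
        assert np.allclose(covered["mean"], 0.8)
        assert np.allclose(covered["se"], 0.0)

    def test_minus_strand_upstream_comes_from_higher_coordinates(self):
        # methylation only beyond the gene end: a − strand gene must see it
        # in its upstream TSS flank
        tiles = uniform_tiles(n=400, level=0.0)
        g = minus_gene()
        tiles.loc[tiles["tile_start"] >= g.end, ["level"]] = 1.0
        tiles.loc[tiles["tile_start"] >= g.end, ["mc_reads"]] = 50
        prof = metaprofile({"g2": g}, tiles, ["g2"], "CG")
        tss = prof[prof["anchor"] == "TSS"].set_index("offset")
        assert tss.loc[-100, "mean"] == pytest.approx(1.0)   # upstream
        assert tss.loc[0, "mean"] == pytest.approx(0.0)      # first body bin

    def test_profile_of_set_is_mean_of_single_gene_profiles(self):
        rng = np.random.default_rng(0)
        tiles = uniform_tiles(n=400)
        tiles["level"] = rng.random(len(tiles))
        tiles["mc_reads"] = tiles["level"] * tiles["total_reads"]
        genes = {"g1": plus_gene(), "g2": minus_gene()}
        both = metaprofile(genes, tiles, ["g1", "g2"], "CG")
        singles = [
            metaprofile(genes, tiles, [g], "CG").set_index(["anchor", "offset"])
            for g in genes
        ]
        merged = both.set_index(["anchor", "offset"])
        for key in merged.index:
            vals = [s.loc[key, "mean"] for s in singles
                    if s.loc[key, "n_genes"] > 0]
            if len(vals) == merged.loc[key, "n_genes"] and vals:
                assert merged.loc[key, "mean"] == pytest.approx(np.mean(vals))

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            metaprofile({}, uniform_tiles(), [], "CG")


class TestTSSClass:
    @pytest.mark.parametrize(
        "level,expected",
        [(0.75, "high"), (0.10, "low"), (0.35, "intermediate")],
    )
    def test_thresholds(self, level, expected):
        tiles = uniform_tiles(context="CHG", level=level)
        assert tss_methylation_class(plus_gene(), tiles, "CHG") == expected

    def test_no_coverage(self):
        tiles = uniform_tiles(context="CHG", n=10)  # ends at 1 kb
        assert tss_methylation_class(plus_gene(), tiles, "CHG") == "no_data"

    def test_minus_strand_window_upstream_of_annotation_end(self):
        g = minus_gene()  # TSS at coordinate end
        tiles = uniform_tiles(context="CG", level=0.0)
        window = (tiles["tile_start"] >= g.end - 400) & (
            tiles["tile_start"] < g.end
        )
        tiles.loc[window, "level"] = 1.0
        tiles.loc[window, "mc_reads"] = 50
        assert tss_methylation_class(g, tiles, "CG") == "high"


class TestProximity:
    features = {"g": ("chr1", 10_000, 14_000)}

    @pytest.mark.parametrize(
        "tile_start,flagged",
        [
            (8_500, True),    # 1.5 kb upstream
            (15_900, True),   # just inside the 2 kb downstream limit
            (11_000, True),   # inside the gene
            (16_000, False),  # first tile fully beyond the 2 kb window
            (7_000, False),   # 2.9 kb upstream
        ],
    )
    def test_island_window(self, tile_start, flagged):
        islands = [MCHHIsland("chr1", tile_start, "B73", 0.4, 20)]
        flags = island_proximity(self.features, islands)
        assert flags["g"] is (True if flagged else False)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 50_000, 20) * 1
        islands = [MCHHIsland("chr1", int(s // 100 * 100), "", 0.3, 15)
                   for s in starts]
        base = island_proximity(self.features, islands)
        shift = 1_000_000
        shifted = island_proximity(
            {"g": ("chr1", 10_000 + shift, 14_000 + shift)},
            [MCHHIsland("chr1", i.tile_start + shift, "", 0.3, 15)
             for i in islands],
        )
        assert base == shifted

    def test_dmr_near_tss_windows(self):
        genes = {"plus": plus_gene(), "minus": minus_gene()}
        catalog = [
            DMRCatalogEntry("chr1", 10_000, "CHG"),   # overlaps + TSS
            DMRCatalogEntry("chr1", 10_300, "CG"),    # 300 bp downstream
            DMRCatalogEntry("chr1", 24_100, "CHH"),   # within 200 of − TSS
        ]
        flags = dmr_near_tss(genes, catalog)
        assert flags.loc["plus", "CHG"] and not flags.loc["plus", "CG"]
        assert not flags.loc["plus", "CHH"]
        assert flags.loc["minus", "CHH"]


class TestEnrichment:
    def test_known_chi2(self):
        # [[10,90],[40,60]]: expected 25/75 per row → chi2 = 24.0
        set_flags = [True] * 10 + [False] * 90
        bg_flags = [True] * 40 + [False] * 60
        chi2, p, enriched = enrichment_test(set_flags, bg_flags)
        assert chi2 == pytest.approx(24.0)
        assert p < 0.01
        assert not enriched  # set proportion is LOWER → direction check

    def test_equal_proportions(self):
        chi2, p, enriched = enrichment_test(
            [True, False] * 20, [True, False] * 50
        )
        assert chi2 == pytest.approx(0.0)
        assert not enriched

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.random(60) < rng.uniform(0.2, 0.8)
            b = rng.random(200) < rng.uniform(0.2, 0.8)
            table = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]],
                             dtype=float)
            n = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / n
            oracle = ((table - expected) ** 2 / expected).sum()
            chi2, _, _ = enrichment_test(a, b)
            assert chi2 == pytest.approx(oracle)

    def test_zero_expected_cell_errors(self):
        with pytest.raises(ValueError, match="exact"):
            enrichment_test([False, False], [False, False])


class TestCorrelation:
    def test_hand_computed_pearson(self):
        res = methylation_expression_correlation(
            [0, 0, 100, 100], [5, 6, 0, 0]
        )
        assert res.r == pytest.approx(-0.9918, abs=1e-3)
        assert res.significant

    def test_constant_expression_undefined(self):
        res = methylation_expression_correlation(
            [0.1, 0.5, 0.9, 0.3], [7, 7, 7, 7]
        )
        assert not res.defined and not res.significant

    def test_perfect_anticorrelation(self):
        res = methylation_expression_correlation(
            [0.0, 0.2, 0.4, 0.8], [8, 6, 4, 0]
        )
        assert res.r == pytest.approx(-1.0)

    def test_too_few_genotypes(self):
        with pytest.raises(ValueError):
            methylation_expression_correlation([1, 2, 3], [3, 2, 1])
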