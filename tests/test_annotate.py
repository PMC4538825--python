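"""Feature assignment, TSS-window localization, expression quintiles,
mark matrix and the HOT/TF-count profile."""

import numpy as np
import pytest

from phantompeaks import (
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    assign_feature,
    binary_mark_matrix,
    expression_quintile_prevalence,
    feature_distribution,
    tf_count_profile,
    tss_window_fraction,
)


@pytest.fixture
def gene_plus():
    # + strand: TSS 10_000, TTS 14_000, exons with one intron
    return GeneModel("gA", "chr1", "+", 10_000, 14_000,
                     [(10_000, 11_000), (13_000, 14_000)])


@pytest.fixture
def gene_minus():
    return GeneModel("gB", "chr1", "-", 30_000, 26_000,
                     [(26_000, 27_000), (29_000, 30_000)])


def peak_at(mid, chrom="chr1", width=200):
    return GenomicInterval(chrom, mid - width // 2, mid + width // 2)


class TestAssignFeature:
    def test_midpoint_at_tss_is_promoter_distance_zero(self, gene_plus):
        fa = assign_feature(peak_at(10_000), [gene_plus])
        assert (fa.category, fa.gene_id, fa.distance_to_tss) == ("promoter", "gA", 0)

    def test_far_peak_is_intergenic(self, gene_plus):
        fa = assign_feature(peak_at(50_000), [gene_plus])
        assert fa.category == "intergenic" and fa.gene_id is None

    def test_promoter_priority_over_intron(self, gene_plus, gene_minus):
        # gene C's intron covers gene A's promoter window
        gene_c = GeneModel("gC", "chr1", "+", 8_000, 12_000,
                           [(8_000, 8_100), (11_900, 12_000)])
        fa = assign_feature(peak_at(9_500), [gene_c, gene_plus])
        assert fa.category == "promoter" and fa.gene_id == "gA"

    def test_tts_exon_intron_categories(self, gene_plus):
        assert assign_feature(peak_at(14_000), [gene_plus]).category == "TTS"
        # inside first exon but outside promoter/TTS windows: 10_000+1000=11_000
        g = GeneModel("gD", "chr1", "+", 10_000, 20_000,
                      [(10_000, 13_000), (17_000, 20_000)])
        assert assign_feature(peak_at(12_000), [g]).category == "exon"
        assert assign_feature(peak_at(15_000), [g]).category == "intron"

    def test_minus_strand_tss(self, gene_minus):
        fa = assign_feature(peak_at(30_000), [gene_minus])
        assert fa.category == "promoter" and fa.distance_to_tss == 0

    def test_tie_broken_by_tss_distance_then_id(self):
        g1 = GeneModel("a", "chr1", "+", 1000, 3000, [(1000, 3000)])
        g2 = GeneModel("b", "chr1", "+", 1400, 3000, [(1400, 3000)])
        fa = assign_feature(peak_at(1300), [g2, g1])
        assert fa.gene_id == "b"  # |1300-1400| < |1300-1000|


class TestDistributions:
    def test_all_tss_catalog(self, gene_plus, gene_minus):
        catalog = IntervalSet([("chr1", 9_900, 10_100), ("chr1", 29_900, 30_100)])
        fracs = feature_distribution(catalog, [gene_plus, gene_minus])
        assert fracs["promoter"] == 1.0
        assert tss_window_fraction(catalog, [gene_plus, gene_minus]) == 1.0

    def test_intergenic_catalog(self, gene_plus):
        catalog = IntervalSet([("chr1", 50_000, 50_200)])
        fracs = feature_distribution(catalog, [gene_plus])
        assert fracs["promoter"] == 0.0 and fracs["intergenic"] == 1.0

    def test_fractions_partition_to_one(self, default_world, default_catalog):
        fracs = feature_distribution(default_catalog, default_world.genes)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sticky_world_catalog_is_promoter_dominated(
        self, default_world, default_catalog
    ):
        """Sticky loci are planted at TSSs, so the derived catalog must be
        promoter-dominated and near-fully inside 4 kb TSS windows."""
        fracs = feature_distribution(default_catalog, default_world.genes)
        assert fracs["promoter"] >= 0.95
        tw = tss_window_fraction(
            default_catalog, default_world.genes,
            chrom_sizes=default_world.config.chrom_sizes(),
        )
        assert tw >= 0.95


class TestQuintiles:
    def _world(self, n=100):
        genes, expr = [], {}
        for i in range(n):
            tss = 5_000 + i * 10_000
            genes.append(
                GeneModel(f"g{i:03d}", "chr1", "+", tss, tss + 2_000,
                          [(tss, tss + 2_000)])
            )
            expr[f"g{i:03d}"] = float(i + 1)
        return genes, ExpressionTable(expr)

    def test_group_sizes_remainder_to_lower_bins(self):
        genes, expr = self._world(103)
        catalog = IntervalSet([("chr1", 0, 100)])
        q = expression_quintile_prevalence(genes, expr, catalog)
        assert q["group_sizes"] == [21, 21, 21, 20, 20]

    def test_top_quintile_only_planting(self):
        genes, expr = self._world(100)
        # plant catalog loci at promoters of the 20 most expressed genes
        rows = [("chr1", g.tss - 100, g.tss + 100) for g in genes[80:]]
        q = expression_quintile_prevalence(genes, expr, IntervalSet(rows))
        assert q["prevalence"][:4] == [0.0, 0.0, 0.0, 0.0]
        assert q["prevalence"][4] == 1.0

    def test_uniform_planting_is_flat(self, rng):
        genes, expr = self._world(100)
        picked = rng.choice(100, size=50, replace=False)
        rows = [("chr1", genes[i].tss - 50, genes[i].tss + 50) for i in picked]
        q = expression_quintile_prevalence(genes, expr, IntervalSet(rows))
        # each quintile ~Binomial(20, 0.5)/20: all within 4 sd of 0.5
        for p in q["prevalence"]:
            assert abs(p - 0.5) <= 4 * np.sqrt(0.25 / 20)

    def test_missing_expression_excluded_and_tallied(self):
        genes, expr = self._world(10)
        expr.values.pop("g003")
        q = expression_quintile_prevalence(genes, expr,
                                           IntervalSet([("chr1", 0, 100)]))
        assert q["n_excluded"] == 1
        assert sum(q["group_sizes"]) == 9


class TestMarksAndHot:
    def _catalog_loci(self):
        return IntervalSet([("chr1", i * 1000, i * 1000 + 200) for i in range(10)])

    def test_self_and_empty_mark_columns(self):
        loci = self._catalog_loci()
        mat, labels = binary_mark_matrix(
            loci, [("self", loci), ("none", IntervalSet())]
        )
        assert labels == ["self", "none"]
        assert mat[:, 0].all() and not mat[:, 1].any()

    def test_matrix_matches_bruteforce(self, rng):
        from helpers import random_interval_set

        loci = self._catalog_loci()
        marks = [
            (f"m{j}", random_interval_set(rng, ["chr1"], 11_000, 15))
            for j in range(4)
        ]
        mat, _ = binary_mark_matrix(loci, marks, min_overlap=20)
        for j, (_, ms) in enumerate(marks):
            s_arr, e_arr = ms.arrays("chr1")
            # oracle against merged mark set
            from helpers import runs_from_mask, mask_from_set

            merged = runs_from_mask(mask_from_set(ms, "chr1", 11_000), "chr1")
            for i, (_, a, b) in enumerate(
                loci.df[["chrom", "start", "end"]].itertuples(index=False)
            ):
                expect = any(min(b, e) - max(a, s) >= 20 for _, s, e in merged)
                assert bool(mat[i, j]) == expect

    def test_duplicate_labels_rejected(self):
        loci = self._catalog_loci()
        with pytest.raises(ValueError, match="duplicate"):
            tf_count_profile(loci, [("t", loci), ("t", loci)])

    def test_hot_threshold_boundary(self):
        loci = IntervalSet([("chr1", 0, 200)])
        cover = IntervalSet([("chr1", 0, 200)])
        eight = [(f"tf{i}", cover) for i in range(8)]
        res8 = tf_count_profile(loci, eight, hot_threshold=8)
        assert res8["hot_fraction"] == 0.0  # 8 is not "more than 8"
        ten = [(f"tf{i}", cover) for i in range(10)]
        res10 = tf_count_profile(loci, ten, hot_threshold=8)
        assert res10["hot_fraction"] == 1.0
        assert res10["histogram"] == {10: 1.0}

    def test_histogram_normalized_over_loci(self, rng):
        from helpers import random_interval_set

        loci = self._catalog_loci()
        tfs = [
            (f"tf{j}", random_interval_set(rng, ["chr1"], 11_000, 10))
            for j in range(6)
        ]
        res = tf_count_profile(loci, tfs)
        assert sum(res["histogram"].values()) == pytest.approx(1.0)
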