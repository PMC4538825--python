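"""Reference-constrained overlap test: pinned cases, exact cross-checks,
reproducibility, and the replicate rank-correlation summary."""

import numpy as np
import pytest

from phantompeaks import (
    CoverageTrack,
    IntervalSet,
    ReferenceRegions,
    overlap_fraction,
    reference_constrained_test,
    replicate_rank_correlation,
    screen_profiles,
)
from phantompeaks.overlap_stats import (
    _NullPlacement,
    _poisson_binomial_upper_tail,
)


def iset(*triples):
    return IntervalSet(list(triples))


@pytest.fixture
def small_ref():
    return ReferenceRegions(iset(("chr1", 0, 3000), ("chr1", 10_000, 14_000)))


class TestOverlapFraction:
    def test_extremes(self):
        cat = iset(("chr1", 100, 300), ("chr1", 900, 1100))
        assert overlap_fraction(cat, cat)[0] == 1.0
        assert overlap_fraction(iset(("chr2", 0, 200)), cat)[0] == 0.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            overlap_fraction(IntervalSet(), iset(("chr1", 0, 100)))


class TestNullPlacement:
    def test_allowed_starts_count(self, small_ref):
        pl = _NullPlacement(small_ref, iset(("chr1", 0, 100)),
                            np.array([200]), 50)
        # region lengths 3000 and 4000: (3000-200+1) + (4000-200+1)
        assert pl.n_allowed(200) == 2801 + 3801

    def test_exact_success_probability_vs_enumeration(self, small_ref):
        """q_w equals brute-force enumeration of every allowed start."""
        catalog = iset(("chr1", 500, 800), ("chr1", 10_500, 10_650))
        w, t = 200, 50
        pl = _NullPlacement(small_ref, catalog, np.array([w]), t)
        n_hit = n_tot = 0
        for rs, re in [(0, 3000), (10_000, 14_000)]:
            for x in range(rs, re - w + 1):
                n_tot += 1
                best = max(
                    min(x + w, ce) - max(x, cs)
                    for cs, ce in [(500, 800), (10_500, 10_650)]
                )
                if best >= t:
                    n_hit += 1
        assert pl.n_allowed(w) == n_tot
        assert pl.q_w[w] == pytest.approx(n_hit / n_tot)

    def test_placements_are_width_preserving_and_inside_reference(self, small_ref, rng):
        widths = np.array([200] * 30 + [900] * 10)
        pl = _NullPlacement(small_ref, iset(("chr1", 500, 700)), widths, 50)
        for _ in range(50):
            placed = pl.sample_positions(widths, rng)
            assert sorted(placed.widths()) == sorted(widths)
            for c, s, e in placed.df[["chrom", "start", "end"]].itertuples(index=False):
                assert any(
                    rs <= s and e <= re
                    for rs, re in [(0, 3000), (10_000, 14_000)]
                )


class TestPoissonBinomial:
    def test_matches_binomial_and_exhaustive(self):
        from scipy import stats

        p = np.full(12, 0.3)
        for t in range(14):
            assert _poisson_binomial_upper_tail(p, t) == pytest.approx(
                stats.binom.sf(t - 1, 12, 0.3), abs=1e-12
            )
        # heterogeneous: exhaustive over all 2^8 outcomes
        probs = np.array([0.1, 0.5, 0.9, 0.2, 0.4, 0.7, 0.3, 0.05])
        for t in range(9):
            exact = 0.0
            for mask in range(2 ** 8):
                bits = [(mask >> i) & 1 for i in range(8)]
                if sum(bits) >= t:
                    pr = np.prod([probs[i] if b else 1 - probs[i]
                                  for i, b in enumerate(bits)])
                    exact += pr
            assert _poisson_binomial_upper_tail(probs, t) == pytest.approx(exact)


class TestReferenceConstrainedTest:
    def test_maximal_statistic_gives_minimal_p(self, small_ref):
        catalog = IntervalSet(
            [("chr1", 100 + i * 140, 200 + i * 140) for i in range(20)]
        )
        rep = reference_constrained_test(
            catalog, catalog, small_ref, min_overlap=50, n_perm=999, seed=1
        )
        assert rep.n_overlapping_catalog == 20
        assert rep.p_perm == pytest.approx(1 / 1000)

    def test_catalog_outside_reference_gives_p_one(self, small_ref):
        catalog = iset(("chr1", 50_000, 50_200))  # disjoint from reference
        query = iset(("chr1", 100, 300))
        rep = reference_constrained_test(
            query, catalog, small_ref, min_overlap=50, n_perm=200, seed=1
        )
        assert rep.n_overlapping_catalog == 0
        assert rep.p_perm == 1.0

    def test_seed_reproducibility(self, small_ref, rng):
        catalog = iset(("chr1", 500, 900), ("chr1", 11_000, 11_400))
        query = IntervalSet(
            [("chr1", int(s), int(s) + 200) for s in rng.integers(0, 2500, 40)]
        )
        a = reference_constrained_test(query, catalog, small_ref, n_perm=500, seed=7)
        b = reference_constrained_test(query, catalog, small_ref, n_perm=500, seed=7)
        assert a.p_perm == b.p_perm
        c = reference_constrained_test(query, catalog, small_ref, n_perm=500, seed=8)
        assert a.seed == 7 and c.seed == 8

    def test_p_analytic_agrees_with_permutation(self, small_ref):
        """On a uniform-width instance the analytic binomial tail and the
        permutation estimate agree within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        catalog = iset(("chr1", 500, 900), ("chr1", 11_000, 11_400))
        pl = _NullPlacement(small_ref, catalog, np.array([200]), 50)
        query = pl.sample_positions(np.full(60, 200), rng)
        rep = reference_constrained_test(
            query, catalog, small_ref, min_overlap=50, n_perm=4999, seed=5
        )
        # MC standard error of the permutation estimate at p_analytic
        se = np.sqrt(rep.p_analytic * (1 - rep.p_analytic) / 5000)
        assert abs(rep.p_perm - rep.p_analytic) <= 4 * se + 2 / 5000

    def test_unplaceable_widths_excluded_not_fatal(self, small_ref):
        query = iset(("chr1", 0, 200), ("chr1", 0, 9000))  # 9 kb fits nowhere
        rep = reference_constrained_test(
            query, iset(("chr1", 500, 700)), small_ref, n_perm=200, seed=0
        )
        assert rep.n_excluded == 1 and rep.n_query == 1
        with pytest.raises(ValueError, match="reference too small"):
            reference_constrained_test(
                iset(("chr1", 0, 9000)), iset(("chr1", 500, 700)),
                small_ref, n_perm=200, seed=0,
            )

    def test_p_perm_nonincreasing_in_observed_overlap(self, small_ref):
        """More observed overlap (same null) can only shrink p."""
        catalog = IntervalSet(
            [("chr1", 100 + i * 300, 300 + i * 300) for i in range(8)]
        )
        ps = []
        for k in (1, 4, 8):
            query = IntervalSet(
                [("chr1", 100 + i * 300, 300 + i * 300) for i in range(k)]
                + [("chr1", 2700 + i * 10, 2900 + i * 10) for i in range(8 - k)]
            )
            rep = reference_constrained_test(
                query, catalog, small_ref, min_overlap=200, n_perm=999, seed=2
            )
            ps.append(rep.p_perm)
        assert ps[0] >= ps[1] >= ps[2]


class TestScreenProfiles:
    def test_extreme_profiles_and_bh_column(self, small_ref):
        catalog = IntervalSet(
            [("chr1", 100 + i * 140, 200 + i * 140) for i in range(15)]
        )
        disjoint = IntervalSet(
            [("chr1", 2200 + i * 30, 2300 + i * 30) for i in range(10)]
        )
        table = screen_profiles(
            [("self", catalog), ("disjoint", disjoint)],
            catalog, small_ref, min_overlap=50, n_perm=199, seed=4,
        )
        assert table.loc[table.label == "self", "fraction"].item() == 1.0
        assert table.loc[table.label == "disjoint", "fraction"].item() == 0.0
        assert table["p_bh"].notna().all()
        assert bool(table.loc[table.label == "self", "flagged"].item())

    def test_planted_overlap_fractions_recovered(self, default_catalog,
                                                 default_reference, rng):
        """Profiles built to overlap a planted fraction of the catalog
        report that fraction (up to peak-count granularity)."""
        loci = default_catalog.loci
        n = 50
        profiles = []
        for frac in (0.0, 0.3, 0.7, 1.0):
            k = int(round(frac * n))
            pick = rng.choice(len(loci), size=n, replace=False)
            rows = []
            for i, li in enumerate(pick):
                row = loci.df.iloc[int(li)]
                if i < k:
                    rows.append((row.chrom, row.start, row.end))
                else:  # shifted clear of the catalog
                    rows.append((row.chrom, row.end + 500, row.end + 700))
            profiles.append((f"f{frac}", IntervalSet(rows)))
        table = screen_profiles(profiles, default_catalog, default_reference,
                                n_perm=199, seed=6)
        for frac, got in zip((0.0, 0.3, 0.7, 1.0), table["fraction"]):
            assert got == pytest.approx(frac, abs=0.06)

    def test_per_profile_errors_do_not_abort_batch(self, small_ref):
        catalog = iset(("chr1", 500, 700))
        bad = iset(("chr1", 0, 9000))  # unplaceable
        good = iset(("chr1", 500, 700))
        table = screen_profiles(
            [("bad", bad), ("good", good)], catalog, small_ref,
            n_perm=199, seed=0,
        )
        assert table.loc[table.label == "bad", "error"].item() != ""
        assert table.loc[table.label == "good", "p_perm"].notna().item()


class TestReplicateRankCorrelation:
    def _track(self, values, label):
        return CoverageTrack(25, {"chr1": np.asarray(values, float)}, label)

    def test_identical_and_reversed_tracks(self, rng):
        v = rng.uniform(1, 10, 400)
        catalog = IntervalSet(
            [("chr1", i * 1000, i * 1000 + 200) for i in range(10)]
        )
        t1 = self._track(v, "a")
        t2 = self._track(v, "b")
        rev = self._track(v.max() + v.min() - v, "c")
        corr = replicate_rank_correlation([t1, t2, rev], catalog)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_matches_rank_then_pearson_oracle(self, rng):
        catalog = IntervalSet(
            [("chr1", i * 500, i * 500 + 100) for i in range(20)]
        )
        t1 = self._track(rng.uniform(0, 5, 400), "x")
        t2 = self._track(rng.uniform(0, 5, 400), "y")
        corr = replicate_rank_correlation([t1, t2], catalog)

        def per_locus(t):
            return np.array([
                t.data["chr1"][s // 25: e // 25].mean()
                for _, s, e in catalog.df[["chrom", "start", "end"]]
                .itertuples(index=False)
            ])

        from scipy import stats

        r1 = stats.rankdata(per_locus(t1))
        r2 = stats.rankdata(per_locus(t2))
        expected = np.corrcoef(r1, r2)[0, 1]
        assert corr.loc["x", "y"] == pytest.approx(expected)

    def test_constant_signal_reported_missing(self):
        catalog = IntervalSet([("chr1", 0, 100), ("chr1", 200, 300)])
        flat = self._track(np.ones(40), "flat")
        varied = self._track(np.arange(40, dtype=float), "varied")
        corr = replicate_rank_correlation([flat, varied], catalog)
        assert np.isnan(corr.loc["flat", "varied"])
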