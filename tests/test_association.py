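"""Binding scores, region randomization, permutation test, distances, KS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromassoc.association import (
    bin_distances,
    classify_bound_top_fraction,
    count_gene_overlaps,
    gene_binding_scores,
    hochberg_adjust,
    ks_compare,
    permutation_overlap_test,
    randomize_regions,
)
from chromassoc.genome import GenomeLayout, IntervalSet
from chromassoc.tracks import SignalTrack

from _oracles import hochberg_oracle, ks_permutation_p
from conftest import iset
from test_tracks import constant_track


class TestGeneBindingScores:
    def test_constant_track_scores_constant(self, small_layout):
        t = constant_track(small_layout, 0.7)
        genes = iset(small_layout, [("chrA", 0, 95, "g1"), ("chrB", 10, 500, "g2")])
        res = gene_binding_scores(t, genes)
        assert np.allclose(res.table["average_log2"], 0.7)

    def test_windowed_average_is_mean_of_window_means(self, small_layout):
        steps = {
            "chrA": (
                np.array([0, 10, 20]),
                np.array([10, 20, 25]),
                np.array([1.0, 2.0, 4.0]),
            )
        }
        t = SignalTrack(small_layout, steps)
        genes = iset(small_layout, [("chrA", 0, 25, "g1")])
        res = gene_binding_scores(t, genes, window_bp=10)
        assert res.table["average_log2"][0] == pytest.approx(7 / 3)

    def test_uncovered_gene_excluded_from_ranking(self, small_layout):
        steps = {"chrA": (np.array([0]), np.array([100]), np.array([1.0]))}
        t = SignalTrack(small_layout, steps)
        genes = iset(small_layout, [("chrA", 0, 100, "g1"), ("chrB", 0, 100, "g2")])
        res = gene_binding_scores(t, genes)
        assert res.n_scored == 1
        assert res.table.loc[1, "average_log2"] != res.table.loc[1, "average_log2"]

    def test_empty_gene_set_rejected(self, small_layout):
        with pytest.raises(ValueError):
            gene_binding_scores(constant_track(small_layout, 0.0), IntervalSet(small_layout))


class TestTopFractionClassification:
    def _table(self, scores, names=None):
        from chromassoc.association import BindingScoreTable

        names = names or [f"g{i:03d}" for i in range(len(scores))]
        df = pd.DataFrame({"gene": names, "average_log2": scores})
        df["rank"] = df["average_log2"].rank(method="dense", ascending=False).astype("Int64")
        df["bound"] = False
        return BindingScoreTable(df, 10)

    def test_top_decile_of_100_distinct(self, rng):
        scores = rng.permutation(100).astype(float)
        res = classify_bound_top_fraction(self._table(list(scores)), 0.10)
        assert res.table["bound"].sum() == 10
        assert set(res.table[res.table["bound"]]["average_log2"]) == set(range(90, 100))
        assert res.min_bound_score == 90.0

    def test_minimum_one_gene_bound(self):
        res = classify_bound_top_fraction(self._table([1.0, 2.0, 3.0, 4.0, 5.0]), 0.10)
        assert res.table["bound"].sum() == 1
        assert res.table.loc[res.table["bound"], "average_log2"].iloc[0] == 5.0

    def test_tie_break_deterministic_and_order_invariant(self, rng):
        scores = [1.0] * 10
        a = classify_bound_top_fraction(self._table(scores), 0.10)
        bound_a = set(a.table[a.table["bound"]]["gene"])
        # shuffle rows; the bound id set must be identical
        tbl = self._table(scores)
        tbl.table = tbl.table.sample(frac=1, random_state=3).reset_index(drop=True)
        b = classify_bound_top_fraction(tbl, 0.10)
        assert set(b.table[b.table["bound"]]["gene"]) == bound_a == {"g000"}

    def test_bound_scores_dominate_unbound(self, rng):
        scores = list(rng.normal(size=57))
        res = classify_bound_top_fraction(self._table(scores), 0.10)
        bound = res.table[res.table["bound"]]["average_log2"]
        unbound = res.table[~res.table["bound"]]["average_log2"].dropna()
        assert bound.min() >= unbound.max()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            classify_bound_top_fraction(self._table([1.0]), 1.5)


class TestRandomizeRegions:
    def test_forced_placement(self):
        layout = GenomeLayout(("chrA",), (500,))
        regions = iset(layout, [("chrA", 100, 600 - 100)])  # length 400 < 500
        layout1 = GenomeLayout(("chrA",), (400,))
        regions1 = iset(layout1, [("chrA", 0, 400)])
        out = randomize_regions(regions1, layout1, np.random.default_rng(0))
        iv = next(iter(out))
        assert (iv.start, iv.end) == (0, 400)

    def test_lengths_preserved(self, small_layout, rng):
        regions = iset(small_layout, [("chrA", 0, 500), ("chrB", 10, 4010), ("chrA", 50, 51)])
        out = randomize_regions(regions, small_layout, rng)
        got = sorted((out.frame["end"] - out.frame["start"]).tolist())
        assert got == [1, 500, 4000]

    def test_too_long_region_rejected(self, small_layout, rng):
        layout = GenomeLayout(("chrA",), (100,))
        regions = iset(layout, [("chrA", 0, 100)])
        big = GenomeLayout(("chrA",), (50,))
        with pytest.raises(ValueError):
            randomize_regions(regions, big, rng)

    def test_start_distribution_uniform(self):
        """Chi-square goodness of fit of placements against the analytic uniform."""
        layout = GenomeLayout(("chrA", "chrB"), (150, 50))
        regions = iset(layout, [("chrA", 0, 41)])  # L=41: 110+10 valid starts
        rng = np.random.default_rng(99)
        counts = np.zeros(120)
        for _ in range(10_000):
            iv = next(iter(randomize_regions(regions, layout, rng)))
            slot = iv.start if iv.chrom == "chrA" else 110 + iv.start
            counts[slot] += 1
        chi2 = ((counts - 10_000 / 120) ** 2 / (10_000 / 120)).sum()
        p = stats.chi2.sf(chi2, df=119)
        assert p > 0.01


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all(self, small_layout):
        genes = iset(small_layout, [("chrA", i * 100, i * 100 + 50) for i in range(10)])
        regions = iset(small_layout, [("chrA", 0, 1000)])
        res = permutation_overlap_test(
            genes, regions, small_layout, n_perm=99, rng=np.random.default_rng(0)
        )
        assert res.observed == 10
        if (res.permuted < 10).all():
            assert res.p_value == pytest.approx(1 / 100)
        assert res.p_value >= 1 / (res.n_perm + 1)

    def test_single_permutation_equal_to_observed(self, small_layout, monkeypatch):
        genes = iset(small_layout, [("chrA", 0, 10_000)])
        regions = iset(small_layout, [("chrA", 0, 10_000)])
        # any single-chromosome-filling region randomizes onto itself
        layout = GenomeLayout(("chrA",), (10_000,))
        genes1 = iset(layout, [("chrA", 0, 10_000)])
        regions1 = iset(layout, [("chrA", 0, 10_000)])
        with pytest.warns(UserWarning):
            res = permutation_overlap_test(
                genes1, regions1, layout, n_perm=1, rng=np.random.default_rng(0)
            )
        assert res.p_value == 1.0
        assert np.isnan(res.z_score)

    def test_alternative_follows_observed_deviation(self, small_layout):
        # genes packed into a region-free corner -> fewer overlaps than chance
        genes = iset(small_layout, [("chrB", i * 10, i * 10 + 5) for i in range(20)])
        regions = iset(small_layout, [("chrA", 0, 3_000)])
        res = permutation_overlap_test(
            genes, regions, small_layout, n_perm=200, rng=np.random.default_rng(1)
        )
        assert res.observed == 0
        assert res.alternative == "less"

    def test_count_gene_overlaps(self, small_layout):
        genes = iset(small_layout, [("chrA", 0, 10), ("chrA", 100, 110), ("chrB", 0, 5)])
        assert count_gene_overlaps(genes, IntervalSet(small_layout)) == 0
        regions = iset(small_layout, [("chrA", 0, 10_000), ("chrB", 0, 6_000)])
        assert count_gene_overlaps(genes, regions) == 3


class TestBinDistances:
    def test_all_overlapping(self):
        dd = bin_distances(np.zeros(5))
        assert dd.counts.tolist() == [5, 0, 0, 0, 0]

    def test_forced_binning(self):
        dd = bin_distances(np.array([0.0, 5_000.0, 50_000.0]))
        assert dd.counts.tolist() == [1, 1, 1, 0, 0]

    def test_edges_are_half_open_on_the_left(self):
        dd = bin_distances(np.array([10_000.0, 10_001.0]))
        assert dd.counts.tolist() == [0, 1, 1, 0, 0]

    def test_no_neighbor_counted_separately(self):
        dd = bin_distances(np.array([0.0, np.nan, np.nan]))
        assert dd.counts.sum() == 1
        assert dd.n_no_neighbor == 2

    def test_random_recount(self, rng):
        d = rng.integers(0, 2_000_000, size=200).astype(float)
        edges = (0, 1_000, 10_000, 1_000_000)
        dd = bin_distances(d, edges)
        want = [
            int((d == 0).sum()),
            int(((d > 0) & (d <= 1_000)).sum()),
            int(((d > 1_000) & (d <= 10_000)).sum()),
            int(((d > 10_000) & (d <= 1_000_000)).sum()),
            int((d > 1_000_000).sum()),
        ]
        assert dd.counts.tolist() == want
        assert dd.counts.sum() == 200

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_distances(np.array([1.0]), (0, 10, 10))
        with pytest.raises(ValueError):
            bin_distances(np.array([1.0]), (5, 10))


class TestKSCompare:
    def test_identical_sample(self, rng):
        x = rng.normal(size=30)
        res = ks_compare(x, x)
        assert res.d_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_supports(self):
        res = ks_compare(np.arange(10.0), np.arange(100.0, 110.0))
        assert res.d_statistic == 1.0

    @pytest.mark.parametrize("na,nb", [(4, 5), (5, 5), (6, 4)])
    def test_small_sample_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(0.8, 1.0, size=nb)
        res = ks_compare(a, b)
        assert res.p_value == pytest.approx(ks_permutation_p(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.array([1.0]))


class TestHochberg:
    def test_single_p_unchanged(self):
        assert hochberg_adjust([0.03]).tolist() == [0.03]

    def test_all_equal(self):
        assert np.allclose(hochberg_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_worked_example(self):
        got = hochberg_adjust([0.01, 0.03, 0.04])
        assert np.allclose(got, [0.03, 0.04, 0.04])

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=20)
        adj = hochberg_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(2, 50)))
        assert np.allclose(hochberg_adjust(p), hochberg_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.5])
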