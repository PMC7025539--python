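import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olivemap.genocall import GenotypeMatrix
from olivemap.linkmap import (GeneticBin, GeneticMap, LinkageGroup,
                              MappingParams, _adjacent_objective,
                              build_parent_map, collapse_bins, compare_maps,
                              distortion_scan, group_markers, kosambi_cM,
                              kosambi_inverse, map_distances, map_stats,
                              order_markers, pairwise_rf_lod, pairwise_tables,
                              parental_patterns, smooth_correct)
from tests.conftest import inject_testcross_flips


def base_id(pattern_id):
    return pattern_id[:-2] if pattern_id.endswith((":m", ":p")) else pattern_id


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

class TestPairwiseRfLod:
    def test_identical_patterns(self):
        a = np.tile([0, 1], 50)
        est = pairwise_rf_lod(a, a)
        assert est.r == 0.0
        assert est.lod == pytest.approx(100 * math.log10(2), abs=1e-9)
        assert est.phase == "coupling"

    def test_complementary_patterns_repulsion(self):
        a = np.tile([0, 1], 50)
        est = pairwise_rf_lod(a, 1 - a)
        assert est.r == 0.0
        assert est.phase == "repulsion"

    def test_two_recombinants_of_ten(self):
        a = np.array([0] * 10)
        b = np.array([0] * 8 + [1] * 2)
        est = pairwise_rf_lod(a, b)
        assert est.r == pytest.approx(0.2)
        expect = 8 * math.log10(1.6) + 2 * math.log10(0.4)
        assert est.lod == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.837, abs=5e-4)

    def test_mle_agrees_with_likelihood_grid(self):
        """Exhaustive grid oracle: r-hat maximises the testcross likelihood
        (n-R)*log(1-r) + R*log(r)."""
        n, R = 10, 2
        grid = np.linspace(1e-6, 0.5, 100_001)
        ll = (n - R) * np.log(1 - grid) + R * np.log(grid)
        assert grid[np.argmax(ll)] == pytest.approx(R / n, abs=1e-4)

    def test_unreliable_below_ten_pairs(self):
        a = np.array([0, 1, 0, 1, -1, -1, -1, -1, -1, -1])
        est = pairwise_rf_lod(a, a)
        assert not est.reliable

    def test_pairwise_tables_match_scalar_op(self):
        rng = np.random.default_rng(4)
        P = rng.integers(0, 2, size=(6, 80)).astype(np.int8)
        P[rng.random(P.shape) < 0.2] = -1
        N, rec, r, lod = pairwise_tables(P)
        for i in range(6):
            for j in range(6):
                est = pairwise_rf_lod(P[i], P[j])
                assert N[i, j] == est.n_informative
                assert r[i, j] == pytest.approx(est.r)
                assert lod[i, j] == pytest.approx(est.lod, abs=1e-9)


# ---------------------------------------------------------------------------
# Grouping / binning / ordering
# ---------------------------------------------------------------------------

class TestGrouping:
    def test_empty_input(self):
        groups, singles = group_markers([], np.empty((0, 0), dtype=np.int8))
        assert groups == [] and singles == []

    def test_rf_threshold_splits_despite_high_lod(self):
        """r = 0.25 with huge LOD still separates (rf_max violated)."""
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 1_000).astype(np.int8)
        b = a.copy()
        flip = rng.choice(1_000, 250, replace=False)
        b[flip] = 1 - b[flip]
        P = np.stack([a, b])
        N, rec, r, lod = pairwise_tables(P)
        assert r[0, 1] == pytest.approx(0.25)
        assert lod[0, 1] > 50
        groups, singles = group_markers(["a", "b"], P)
        assert groups == [] and singles == ["a", "b"]

    def test_error_free_grouping_matches_chromosomes(self, small_cross):
        _, genome, pop = small_cross
        chrom_of = {m.marker_id: m.chrom for m in genome.markers}
        for parent in ("mother", "father"):
            pat = parental_patterns(pop.genotypes, parent)
            groups, singles = group_markers(list(pat.index), pat.to_numpy())
            assert singles == []
            assert len(groups) == 3
            for g in groups:
                assert len({chrom_of[base_id(m)] for m in g}) == 1


class TestCollapseBins:
    def test_identical_patterns_one_bin(self):
        a = np.tile([0, 1], 25).astype(np.int8)
        bins = collapse_bins(["m2", "m1"], np.stack([a, a]))
        assert len(bins) == 1
        assert bins[0].representative == "m1"  # lexicographic tie-break
        assert bins[0].markers == ["m1", "m2"]

    def test_one_call_difference_two_bins(self):
        a = np.tile([0, 1], 25).astype(np.int8)
        b = a.copy()
        b[0] = 1 - b[0]
        assert len(collapse_bins(["m1", "m2"], np.stack([a, b]))) == 2

    def test_representative_has_fewest_missing(self):
        a = np.tile([0, 1], 25).astype(np.int8)
        a2 = a.copy()
        a2[:5] = -1
        bins = collapse_bins(["m1", "m2"], np.stack([a2, a]))
        assert bins[0].representative == "m2"

    def test_bin_count_equals_distinct_pattern_count(self):
        """Brute-force dedup oracle on duplicated error-free markers: the
        bin count equals the number of phase-canonical distinct patterns."""
        rng = np.random.default_rng(9)
        base = rng.integers(0, 2, size=(12, 120)).astype(np.int8)
        dup = np.concatenate([base, base[: 6], 1 - base[:3]])  # copies + flips
        ids = [f"m{i:02d}" for i in range(len(dup))]
        canon = {tuple(p if p[0] == 0 else 1 - p) for p in dup}
        bins = collapse_bins(ids, dup)
        assert len(bins) == len(canon)


class TestOrdering:
    def test_single_bin_unchanged(self):
        b = GeneticBin("m1", ["m1"], pattern=np.tile([0, 1], 25).astype(np.int8))
        assert order_markers([b]) == [b]

    def test_three_bins_match_exhaustive_search(self):
        """The heuristic's adjacent-recombination total equals the optimum
        found by brute force over all 3 orders."""
        rng = np.random.default_rng(12)
        a = rng.integers(0, 2, 200).astype(np.int8)
        b, c = a.copy(), a.copy()
        b[rng.choice(200, 5, replace=False)] ^= 1
        c[rng.choice(200, 12, replace=False)] ^= 1
        bins = collapse_bins(["a", "b", "c"], np.stack([a, b, c]))
        assert len(bins) == 3
        ordered = order_markers(bins)
        P = np.stack([x.pattern for x in bins])
        _, rec, _, _ = pairwise_tables(P)
        best = min(_adjacent_objective(o, rec)
                   for o in ([0, 1, 2], [0, 2, 1], [1, 0, 2]))
        got_idx = [[x.representative for x in bins].index(x.representative)
                   for x in ordered]
        assert _adjacent_objective(got_idx, rec) == best

    def test_disconnected_graph_errors_with_subsets(self):
        a = np.array([0, 1] * 30 + [-1] * 60, dtype=np.int8)
        b = np.array([-1] * 60 + [0, 1] * 30, dtype=np.int8)
        bins = [GeneticBin("m1", ["m1"], pattern=a),
                GeneticBin("m2", ["m2"], pattern=b)]
        with pytest.raises(ValueError, match="disconnected"):
            order_markers(bins)

    def test_error_free_order_recovered_up_to_reversal(self, maternal_only_cross):
        _, genome, pop = maternal_only_cross
        gmap, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        assert len(gmap.groups) == 1
        truepos = {m.marker_id: m.pos_female for m in genome.markers}
        seq = [np.mean([truepos[base_id(m)] for m in b.markers])
               for b in gmap.groups[0].bins]
        increasing = all(x <= y for x, y in zip(seq, seq[1:]))
        decreasing = all(x >= y for x, y in zip(seq, seq[1:]))
        assert increasing or decreasing

    def test_orientation_canonical_and_deterministic(self, maternal_only_cross):
        _, _, pop = maternal_only_cross
        gmap1, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        gmap2, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        r1 = [b.representative for b in gmap1.groups[0].bins]
        r2 = [b.representative for b in gmap2.groups[0].bins]
        assert r1 == r2
        assert r1[0] < r1[-1]


# ---------------------------------------------------------------------------
# Kosambi function and distances
# ---------------------------------------------------------------------------

class TestKosambi:
    def test_zero(self):
        assert kosambi_cM(0.0) == 0.0

    def test_quarter(self):
        assert kosambi_cM(0.25) == pytest.approx(25 * math.log(3), abs=1e-9)
        assert kosambi_cM(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_small_r_series_oracle(self):
        """d = 100*(r + 4r^3/3 + 16r^5/5 + ...) for small r."""
        r = 0.01
        series = 100 * (r + 4 * r ** 3 / 3 + 16 * r ** 5 / 5)
        assert kosambi_cM(r) == pytest.approx(series, abs=1e-9)
        assert kosambi_cM(r) == pytest.approx(1.00013, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            kosambi_cM(-0.01)

    @given(st.floats(0.0, 0.499))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_with_inverse(self, r):
        assert kosambi_inverse(kosambi_cM(r)) == pytest.approx(r, abs=1e-9)

    @given(st.floats(0.0, 0.49), st.floats(1e-6, 0.009))
    @settings(max_examples=100, deadline=None)
    def test_strictly_monotone(self, r, dr):
        assert kosambi_cM(r + dr) > kosambi_cM(r)


class TestMapDistances:
    @staticmethod
    def _bins_from_patterns(patterns):
        return [GeneticBin(f"m{i}", [f"m{i}"], pattern=np.asarray(p, np.int8))
                for i, p in enumerate(patterns)]

    def test_identical_bins_zero_length(self):
        a = np.tile([0, 1], 50)
        bins = self._bins_from_patterns([a, a, a])
        assert map_distances(bins)[-1].position_cM == 0.0

    def test_three_bins_r01_each(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 100).astype(np.int8)
        b, c = a.copy(), None
        b[:10] ^= 1
        c = b.copy()
        c[90:] ^= 1
        bins = self._bins_from_patterns([a, b, c])
        out = map_distances(bins)
        expect = 2 * 25 * math.log(1.2 / 0.8)
        assert out[-1].position_cM == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(20.27, abs=5e-3)

    def test_positions_non_decreasing(self, maternal_only_cross):
        _, _, pop = maternal_only_cross
        gmap, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        pos = [b.position_cM for b in gmap.groups[0].bins]
        assert all(x <= y for x, y in zip(pos, pos[1:]))
        assert pos[0] == 0.0


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

class TestSmoothCorrect:
    def test_error_free_data_nearly_untouched(self, maternal_only_cross):
        """Error-free data is left essentially alone.  The removals that do
        occur are genuine single-marker double-crossover segments, which the
        no-interference crossover model produces at a low rate and which are
        data-indistinguishable from isolated errors; they stay below 0.3%
        of calls."""
        _, _, pop = maternal_only_cross
        _, removals = build_parent_map(pop.genotypes, "mother", smooth=True)
        assert len(removals) / pop.genotypes.calls.size < 0.003

    def test_single_singleton_removed_first_iteration(self, maternal_only_cross):
        _, _, pop = maternal_only_cross
        gm2, flips = inject_testcross_flips(pop.genotypes, 0.0, seed=0)
        mid = pop.genotypes.marker_ids[30]
        ind = pop.genotypes.individuals[50]
        pair = ("A", "H") if gm2.father[mid] == "A" else ("H", "B")
        cur = gm2.calls.at[mid, ind]
        gm2.calls.at[mid, ind] = pair[0] if cur == pair[1] else pair[1]
        _, removals = build_parent_map(gm2, "mother", smooth=True)
        assert (mid, ind) in removals

    def test_bulk_error_scrub_recall_and_collateral(self, maternal_only_cross):
        """Neighbour-consensus oracle via the truth log: >= 80% of injected
        1% singleton flips removed, < 1% of correct calls removed."""
        _, _, pop = maternal_only_cross
        gm2, flips = inject_testcross_flips(pop.genotypes, 0.01, seed=5)
        _, removals = build_parent_map(gm2, "mother", smooth=True)
        removed = set(removals)
        tp = len(removed & flips)
        fp = len(removed - flips)
        n_correct = gm2.calls.size - len(flips)
        assert tp / len(flips) >= 0.80
        assert fp / n_correct < 0.01

    def test_smoothing_shrinks_inflated_map_length(self, maternal_only_cross):
        _, _, pop = maternal_only_cross
        gm2, _ = inject_testcross_flips(pop.genotypes, 0.01, seed=6)
        len_clean = map_stats(build_parent_map(pop.genotypes, "mother",
                                               smooth=False)[0]).total_length
        len_err = map_stats(build_parent_map(gm2, "mother",
                                             smooth=False)[0]).total_length
        len_smooth = map_stats(build_parent_map(gm2, "mother",
                                                smooth=True)[0]).total_length
        assert len_err > len_clean  # errors inflate the map
        assert abs(len_smooth - len_clean) < abs(len_err - len_clean)


# ---------------------------------------------------------------------------
# Distortion
# ---------------------------------------------------------------------------

class TestDistortionScan:
    @staticmethod
    def _testcross_gm(a, b):
        calls = pd.DataFrame([["A"] * a + ["H"] * b],
                             index=["m1"],
                             columns=[f"o{i}" for i in range(a + b)])
        return GenotypeMatrix(calls, pd.Series({"m1": "H"}),
                              pd.Series({"m1": "A"}),
                              pd.Series({"m1": "maternal_testcross"}))

    def test_counts_56_47_not_flagged(self):
        out = distortion_scan(self._testcross_gm(56, 47))
        assert out.loc["m1", "chi2"] == pytest.approx(81 / 103, abs=1e-9)
        assert round(out.loc["m1", "chi2"], 2) == 0.79
        assert not out.loc["m1", "flagged"]

    def test_balanced_zero(self):
        out = distortion_scan(self._testcross_gm(50, 50))
        assert out.loc["m1", "chi2"] == 0.0
        assert not out.loc["m1", "flagged"]

    def test_70_30_flagged(self):
        out = distortion_scan(self._testcross_gm(70, 30))
        assert out.loc["m1", "chi2"] == pytest.approx(16.0)
        assert out.loc["m1", "flagged"]  # 16.0 > 3.841 critical value

    def test_flag_rate_near_alpha_on_undistorted_data(self, small_cross):
        _, _, pop = small_cross
        out = distortion_scan(pop.genotypes)
        rate = out["flagged"].mean()
        n = len(out)
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 4 * se

    def test_bonferroni_reduces_flags(self, small_cross):
        _, _, pop = small_cross
        plain = distortion_scan(pop.genotypes)["flagged"].sum()
        bonf = distortion_scan(pop.genotypes, bonferroni=True)["flagged"].sum()
        assert bonf <= plain


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

def _anchor_map(parent, positions, lg=1, reverse_slice=None, ids=None):
    ids = ids or [f"x{i:02d}" for i in range(len(positions))]
    order = list(range(len(positions)))
    if reverse_slice:
        a, b = reverse_slice
        order = order[:a] + order[a:b][::-1] + order[b:]
    bins = [GeneticBin(ids[idx], [ids[idx]], position_cM=positions[rank])
            for rank, idx in enumerate(order)]
    return GeneticMap(parent=parent, groups=[LinkageGroup(lg_id=lg, bins=bins)])


class TestCompareMaps:
    positions = [float(5 * i) for i in range(21)]  # 0..100 cM

    def test_identical_orders_clean(self):
        rep = compare_maps(_anchor_map("mother", self.positions),
                           _anchor_map("father", self.positions))
        assert rep.inversions == []
        assert rep.translocations == []
        assert rep.lg_pairs == {1: 1}

    def test_reversed_30cM_segment_one_inversion(self):
        rep = compare_maps(_anchor_map("mother", self.positions),
                           _anchor_map("father", self.positions,
                                       reverse_slice=(6, 13)))
        assert len(rep.inversions) == 1
        inv = rep.inversions[0]
        assert inv.extent_a == (30.0, 60.0)
        assert inv.span_a == pytest.approx(30.0)
        assert len(inv.anchors) >= 2

    def test_invariant_to_marker_naming(self):
        ids = [f"z{i:02d}" for i in range(21)][::-1]  # reversed naming
        rep = compare_maps(
            _anchor_map("mother", self.positions, ids=ids),
            _anchor_map("father", self.positions, ids=ids,
                        reverse_slice=(6, 13)))
        assert len(rep.inversions) == 1
        assert rep.inversions[0].extent_a == (30.0, 60.0)

    def test_translocated_anchor_reported(self):
        a = _anchor_map("mother", self.positions)
        bins = [GeneticBin("x05", ["x05"], position_cM=0.0)]
        b = _anchor_map("father", [p for i, p in enumerate(self.positions)
                                   if i != 5],
                        ids=[f"x{i:02d}" for i in range(21) if i != 5])
        b.groups.append(LinkageGroup(lg_id=2, bins=bins))
        rep = compare_maps(a, b)
        assert rep.translocations == ["x05"]

    def test_unalignable_group_with_single_anchor(self):
        a = _anchor_map("mother", [0.0], ids=["x00"])
        b = _anchor_map("father", [0.0], ids=["x00"])
        rep = compare_maps(a, b)
        assert rep.unalignable == [1]

    def test_built_maps_share_abxcd_anchors(self, small_cross):
        _, genome, pop = small_cross
        gmap_m, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        gmap_f, _ = build_parent_map(pop.genotypes, "father", smooth=False)
        rep = compare_maps(gmap_m, gmap_f)
        n_abxcd = sum(m.seg_class == "fully_informative"
                      for m in genome.markers)
        assert len(rep.anchors) == n_abxcd
        assert rep.translocations == []
        assert len(rep.lg_pairs) == 3


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

class TestMapStats:
    def test_empty_map_zeros(self):
        s = map_stats(GeneticMap(parent="mother", groups=[]))
        assert s.total_markers == 0
        assert s.total_length == 0.0
        assert s.mean_bin_spacing == 0.0

    def test_counts_add_up(self, small_cross):
        _, _, pop = small_cross
        gmap, _ = build_parent_map(pop.genotypes, "mother", smooth=False)
        s = map_stats(gmap)
        assert s.total_markers == sum(g.n_markers for g in gmap.groups)
        assert s.total_bins == sum(len(g.bins) for g in gmap.groups)
        assert s.total_length == pytest.approx(
            sum(g.bins[-1].position_cM for g in gmap.groups))
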