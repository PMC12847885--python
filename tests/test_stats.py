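"""Ranking, aliquot partitioning, quantile slices and two-group tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ribostress as rs


def _de(triples):
    return [rs.DERecord(i, l, p) for i, l, p in triples]


class TestRankByPvalue:
    def test_significant_stratum_sorted_ascending(self):
        ranked = rs.rank_by_pvalue(_de([("a", 0, .04), ("b", 0, .01), ("c", 0, .2)]), .05,
                                   "significant")
        assert ranked.ids == ["b", "a"]

    def test_ties_break_by_feature_id(self):
        ranked = rs.rank_by_pvalue(_de([("z", 0, .01), ("a", 0, .01)]), .05, "significant")
        assert ranked.ids == ["a", "z"]

    def test_zero_pvalues_rank_first(self):
        ranked = rs.rank_by_pvalue(_de([("a", 0, .001), ("b", 0, 0.0)]), .05, "significant")
        assert ranked.ids == ["b", "a"]

    def test_empty_stratum_is_an_error(self):
        with pytest.raises(rs.InputValidationError, match="significant"):
            rs.rank_by_pvalue(_de([("a", 0, .5)]), .05, "significant")

    def test_boundary_pvalue_goes_nonsignificant(self):
        ranked = rs.rank_by_pvalue(_de([("a", 0, .05), ("b", 0, .6)]), .05, "nonsignificant")
        assert ranked.ids == ["a", "b"]


class TestPartitionAliquots:
    def _ranked(self, n):
        recs = _de([(f"x{i:05d}", 0.0, i / (2 * n + 1) * 0.04) for i in range(n)])
        return rs.rank_by_pvalue(recs, 0.05, "significant")

    def test_reported_decile_sizes_at_9045(self):
        part = rs.partition_aliquots(self._ranked(9045), 10)
        assert part.sizes == [905] * 5 + [904] * 5
        assert max(part.sizes) == 905 and min(part.sizes) == 904

    def test_singleton_groups(self):
        assert rs.partition_aliquots(self._ranked(10), 10).sizes == [1] * 10

    def test_remainder_goes_to_smallest_p_groups(self):
        assert rs.partition_aliquots(self._ranked(23), 10).sizes == [3, 3, 3] + [2] * 7

    def test_too_few_features_is_an_error(self):
        with pytest.raises(rs.InputValidationError):
            rs.partition_aliquots(self._ranked(5), 10)

    @given(st.integers(min_value=1, max_value=400), st.integers(min_value=1, max_value=20))
    def test_partition_conserves_order_and_count(self, n, k):
        if n < k:
            return
        ranked = self._ranked(n)
        part = rs.partition_aliquots(ranked, k)
        assert sum(part.sizes) == n
        assert list(itertools.chain.from_iterable(part.groups)) == ranked.ids
        assert all(a >= b for a, b in zip(part.sizes, part.sizes[1:]))
        assert max(part.sizes) - min(part.sizes) <= 1


class TestQuantileSlice:
    def test_reported_25pct_slice_of_478(self):
        assert rs.slice_size(478, 0.25) == 120  # 119.5 rounds away from zero

    def test_small_fraction_floor_of_one(self):
        assert rs.slice_size(40, 0.025) == 1

    def test_rounding_rule_at_2_5pct_of_478(self):
        assert rs.slice_size(478, 0.025) == 12  # 11.95 -> 12

    def test_top_and_bottom_take_opposite_ends(self):
        recs = _de([(f"x{i}", 0, 0.001 * (i + 1)) for i in range(8)])
        ranked = rs.rank_by_pvalue(recs, 0.05, "significant")
        assert rs.quantile_slice(ranked, 0.25, "top") == ranked.ids[:2]
        assert rs.quantile_slice(ranked, 0.25, "bottom") == ranked.ids[-2:]

    def test_fraction_bounds(self):
        ranked = rs.rank_by_pvalue(_de([("a", 0, .01), ("b", 0, .02)]), .05, "significant")
        for frac in (0.0, 0.6, -0.1):
            with pytest.raises(rs.ConfigError):
                rs.quantile_slice(ranked, frac, "top")

    def test_abs_lfc_ranking_descending_with_id_ties(self):
        recs = _de([("a", -3.0, .01), ("b", 3.0, .01), ("c", 1.0, .01)])
        ranked = rs.rank_by_abs_lfc(recs)
        assert ranked.ids == ["a", "b", "c"]

    @given(st.integers(min_value=4, max_value=300),
           st.floats(min_value=0.01, max_value=0.25),
           st.floats(min_value=0.26, max_value=0.5))
    def test_slice_nesting(self, n, f1, f2):
        recs = _de([(f"x{i:04d}", 0, 0.0001 * (i + 1)) for i in range(n)])
        ranked = rs.rank_by_pvalue(recs, 0.05, "significant")
        top1 = rs.quantile_slice(ranked, f1, "top")
        top2 = rs.quantile_slice(ranked, f2, "top")
        assert top2[: len(top1)] == top1


class TestCompareGroups:
    def test_fully_tied_groups(self):
        c = rs.compare_groups([1, 2, 3], [1, 2, 3], "rank")
        assert c.direction == "none"
        assert c.pvalue == pytest.approx(1.0)

    def test_identical_constant_groups(self):
        c = rs.compare_groups([5, 5, 5], [5, 5])
        assert c.pvalue == 1.0 and c.direction == "none"

    def test_exact_p_for_complete_separation(self):
        # U = 0; 2 of the 20 rank arrangements are at least as extreme
        c = rs.compare_groups([1, 2, 3], [4, 5, 6])
        assert c.pvalue == pytest.approx(0.1, abs=1e-12)
        assert c.direction == "a<b"

    def test_small_groups_match_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for n_a, n_b in [(2, 3), (3, 4), (4, 4), (2, 6)]:
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            c = rs.compare_groups(a, b)
            assert c.pvalue == pytest.approx(_enumerated_p(a, b), abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=40)
        for method in ("rank", "welch"):
            c1 = rs.compare_groups(a, b, method)
            c2 = rs.compare_groups(b, a, method)
            assert c1.pvalue == pytest.approx(c2.pvalue, rel=1e-12)
            assert {c1.direction, c2.direction} == {"a>b", "a<b"}

    def test_groups_below_two_values_error(self):
        with pytest.raises(rs.InputValidationError):
            rs.compare_groups([1.0], [1.0, 2.0])

    def test_welch_detects_shift(self):
        rng = np.random.default_rng(4)
        c = rs.compare_groups(rng.normal(1.0, 1, 100), rng.normal(0, 1, 100), "welch")
        assert c.pvalue < 0.001 and c.direction == "a>b"


def _enumerated_p(a, b):
    """Brute-force two-sided Mann-Whitney p over all rank splits."""
    pooled = np.concatenate([a, b])
    order = {v: r for r, v in enumerate(sorted(pooled))}
    ranks_a = [order[v] for v in a]
    m = len(a) * len(b)
    u_obs = sum(sum(1 for v in b if order[v] < r) for r in ranks_a)
    lo = min(u_obs, m - u_obs)
    count = total = 0
    all_ranks = range(len(pooled))
    for combo in itertools.combinations(all_ranks, len(a)):
        u = sum(r - i for i, r in enumerate(sorted(combo)))
        total += 1
        if u <= lo or u >= m - lo:
            count += 1
    return count / total


class TestAdjustBH:
    def test_hand_worked_step_up(self):
        assert rs.adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test_unchanged(self):
        assert rs.adjust_bh([0.2]) == [pytest.approx(0.2)]

    def test_empty_input(self):
        assert rs.adjust_bh([]) == []

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_adjusted_dominates_raw_and_caps_at_one(self, pvals):
        adj = rs.adjust_bh(pvals)
        assert len(adj) == len(pvals)
        assert all(a >= p - 1e-12 and a <= 1.0 for a, p in zip(adj, pvals))
        # order of the input maps through: sorting by raw p sorts adjusted p
        pairs = sorted(zip(pvals, adj))
        assert all(x[1] <= y[1] + 1e-12 for x, y in zip(pairs, pairs[1:]))
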