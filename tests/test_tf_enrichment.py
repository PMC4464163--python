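import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regulonrank.errors import ConsistencyError
from regulonrank.tf_enrichment import (
    ContingencyTable,
    build_contingency,
    compare_conditions,
    fisher_exact,
    rank_tfs,
)

from oracles import fisher_two_sided_exact


class TestBuildContingency:
    def test_worked_partition(self):
        universe = {f"g{i}" for i in range(1, 11)}
        targets = {"g1", "g2", "g3", "g4"}
        degs = {"g1", "g2", "g5"}
        tab = build_contingency(targets, degs, universe)
        assert (tab.a, tab.b, tab.c, tab.d) == (2, 2, 1, 5)
        assert tab.n == 10

    def test_no_degs(self):
        universe = {f"g{i}" for i in range(8)}
        targets = {"g0", "g1"}
        tab = build_contingency(targets, set(), universe)
        assert (tab.a, tab.b, tab.c, tab.d) == (0, 2, 0, 6)

    def test_targets_outside_universe_rejected(self):
        with pytest.raises(ConsistencyError):
            build_contingency({"gX"}, set(), {"g1"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_cells_partition_the_universe(self, seed):
        rng = np.random.default_rng(seed)
        universe = {f"g{i}" for i in range(40)}
        pool = sorted(universe)
        targets = set(rng.choice(pool, size=rng.integers(0, 20), replace=False))
        degs = set(rng.choice(pool, size=rng.integers(0, 20), replace=False))
        tab = build_contingency(targets, degs, universe)
        assert tab.n == len(universe)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 0, 2)


class TestFisherExact:
    def test_symmetric_unit_table_is_one(self):
        # support {0,1,2}, pmf (1/6, 2/3, 1/6); observed point has maximal
        # mass so the two-sided sum covers the whole support
        assert fisher_exact((1, 1, 1, 1)) == pytest.approx(1.0)

    def test_small_table_matches_rational_enumeration(self):
        got = fisher_exact((2, 2, 1, 5))
        want = float(fisher_two_sided_exact(2, 2, 1, 5))
        assert got == pytest.approx(want, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_scipy_reference(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        got = fisher_exact((a, b, c, d))
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert got == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_extreme_tail_against_scipy(self):
        # regulon-scale depleted table with a P far beyond where naive
        # summation underflows
        table = (54, 265, 3750, 5788)
        got = fisher_exact(table)
        ref = stats.fisher_exact([[54, 265], [3750, 5788]]).pvalue
        assert got < 1e-16
        assert got == pytest.approx(ref, rel=1e-9)

    def test_depleted_table_is_small_not_one(self):
        tab = ContingencyTable(54, 265, 3750, 5788)
        assert tab.direction == "depleted"
        assert fisher_exact(tab) < 1e-10

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_transposition_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact((a, b, c, d))
        assert fisher_exact((a, c, b, d)) == pytest.approx(p, rel=1e-9)
        assert fisher_exact((d, c, b, a)) == pytest.approx(p, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_one_sided_tails_share_observed_mass(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        gt = fisher_exact((a, b, c, d), "greater")
        lt = fisher_exact((a, b, c, d), "less")
        assert gt + lt >= 1.0 - 1e-12

    def test_unknown_alternative(self):
        with pytest.raises(ValueError):
            fisher_exact((1, 1, 1, 1), "both")


class TestRankTFs:
    def test_perfect_regulon_ranks_first(self):
        universe = {f"g{i}" for i in range(20)}
        degs = {"g0", "g1", "g2", "g3", "g4"}
        tf_sets = {"Tperfect": set(degs), "Trandom": {"g5", "g6", "g7"}}
        results = rank_tfs(tf_sets, degs, universe)
        assert results[0].tf_id == "Tperfect"
        assert results[0].rank == 1
        # minimum achievable p: the single most extreme table
        want = float(fisher_two_sided_exact(5, 0, 0, 15))
        assert results[0].p_value == pytest.approx(want, rel=1e-9)

    def test_ties_break_lexicographically(self):
        universe = {f"g{i}" for i in range(12)}
        degs = {"g0", "g1", "g2"}
        same = {"g0", "g1", "g5"}
        results = rank_tfs({"Tb": set(same), "Ta": set(same)}, degs, universe)
        assert [r.tf_id for r in results] == ["Ta", "Tb"]
        assert results[0].p_value == results[1].p_value
        assert [r.rank for r in results] == [1, 2]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(8)
        universe = {f"g{i}" for i in range(60)}
        pool = sorted(universe)
        degs = set(rng.choice(pool, size=15, replace=False))
        tf_sets = {
            f"T{i}": set(rng.choice(pool, size=rng.integers(2, 20),
                                    replace=False))
            for i in range(12)
        }
        results = rank_tfs(tf_sets, degs, universe)
        assert sorted(r.rank for r in results) == list(range(1, 13))
        assert all(
            results[i].p_value <= results[i + 1].p_value
            for i in range(len(results) - 1)
        )

    def test_significance_flag_is_strict_raw_p(self):
        universe = {f"g{i}" for i in range(30)}
        degs = {f"g{i}" for i in range(10)}
        results = rank_tfs({"T1": set(degs)}, degs, universe, tf_alpha=0.01)
        assert results[0].significant == (results[0].p_value < 0.01)

    def test_empty_mapping_warns_and_returns_empty(self, caplog):
        assert rank_tfs({}, set(), {"g1"}) == []

    def test_empty_intersected_regulons_excluded(self):
        universe = {"g1", "g2"}
        results = rank_tfs({"T1": {"gX"}}, {"g1"}, universe)
        assert results == []


class TestCompareConditions:
    def _ranked(self, ids):
        universe = {f"g{i}" for i in range(40)} | set()
        degs = {f"g{i}" for i in range(8)}
        # build one real result list whose order follows `ids`
        out = []
        for i, tf in enumerate(ids):
            res = rank_tfs({tf: {f"g{i % 8}"}}, degs, universe)
            r = res[0]
            r.rank = i + 1
            out.append(r)
        return out

    def test_identical_lists_fully_shared(self):
        ids = [f"T{i}" for i in range(10)]
        ranked = self._ranked(ids)
        cmp = compare_conditions(ranked, ranked, top_k=10)
        assert cmp.shared == set(ids)
        assert not cmp.only_a and not cmp.only_b

    def test_disjoint_lists(self):
        a = self._ranked([f"A{i}" for i in range(5)])
        b = self._ranked([f"B{i}" for i in range(5)])
        cmp = compare_conditions(a, b, top_k=5)
        assert cmp.shared == set()

    def test_constructed_seven_of_ten_overlap(self):
        shared = [f"S{i}" for i in range(7)]
        a = self._ranked(shared + ["A1", "A2", "A3"])
        b = self._ranked(["B1"] + shared[:4] + ["B2", "B3"] + shared[4:])
        cmp = compare_conditions(a, b, top_k=10)
        assert len(cmp.shared) == 7
        assert cmp.only_a == {"A1", "A2", "A3"}
        assert cmp.only_b == {"B1", "B2", "B3"}

    def test_top_k_beyond_length_uses_full_list(self):
        a = self._ranked(["T1", "T2"])
        cmp = compare_conditions(a, a, top_k=10)
        assert cmp.shared == {"T1", "T2"}

    def test_top_k_must_be_positive(self):
        with pytest.raises(ValueError):
            compare_conditions([], [], top_k=0)
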