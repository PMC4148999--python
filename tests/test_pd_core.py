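"""PD arithmetic, contribution scores, greedy selection and the oracle."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pdselect import (
    brute_force_select,
    greedy_select,
    parse_newick,
    pd,
    pd_coverage,
    total_branch_length,
    unique_contribution,
    write_leaf_list,
)
from pdselect.errors import OracleRefusalError, SelectionError, UnknownTaxonError
from pdselect.simulate import SimulationSpec, simulate_yule_tree

from conftest import oracle_pd, star_newick


class TestPd:
    @pytest.mark.parametrize(
        "taxa,mode,expected",
        [
            ({"C"}, "rooted", 5.0),          # 3 + 2 on the root path
            ({"A", "C"}, "unrooted", 7.0),   # spanning subgraph 1+1+2+3
            ({"C"}, "unrooted", 0.0),
            (set(), "rooted", 0.0),
            (set(), "unrooted", 0.0),
            ({"A", "B", "C", "D"}, "rooted", 10.0),
            ({"A", "B", "C", "D"}, "unrooted", 10.0),
        ],
    )
    def test_worked_examples(self, four_leaf_tree, taxa, mode, expected):
        assert pd(four_leaf_tree, taxa, mode) == expected

    def test_unknown_taxon_named(self, four_leaf_tree):
        with pytest.raises(UnknownTaxonError, match="Zorp"):
            pd(four_leaf_tree, {"A", "Zorp"})

    @given(seed=st.integers(0, 5000), n=st.integers(3, 25), data=st.data())
    @settings(max_examples=80, deadline=None)
    def test_matches_independent_oracle(self, seed, n, data):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed))
        labels = write_leaf_list(tree)
        taxa = set(data.draw(st.lists(st.sampled_from(labels), max_size=n)))
        for mode in ("rooted", "unrooted"):
            assert math.isclose(
                pd(tree, taxa, mode), oracle_pd(tree, taxa, mode), rel_tol=1e-12, abs_tol=1e-12
            )

    @given(seed=st.integers(0, 5000), n=st.integers(3, 20), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_the_taxon_set(self, seed, n, data):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed))
        labels = write_leaf_list(tree)
        small = set(data.draw(st.lists(st.sampled_from(labels), max_size=n)))
        extra = set(data.draw(st.lists(st.sampled_from(labels), max_size=n)))
        for mode in ("rooted", "unrooted"):
            assert pd(tree, small, mode) <= pd(tree, small | extra, mode) + 1e-12

    @given(seed=st.integers(0, 5000), n=st.integers(3, 20), scale=st.floats(0.1, 100))
    @settings(max_examples=40, deadline=None)
    def test_pd_of_all_leaves_is_total_length(self, seed, n, scale):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed, birth_rate=scale))
        labels = set(write_leaf_list(tree))
        for mode in ("rooted", "unrooted"):
            assert math.isclose(pd(tree, labels, mode), total_branch_length(tree), rel_tol=1e-12)


class TestUniqueContribution:
    def test_worked_example(self, four_leaf_tree):
        # dropping B loses only its pendant branch: 10 - pd({A,C,D}) = 2
        assert unique_contribution(four_leaf_tree, "B", "unrooted") == 2.0

    def test_cherry_collapse(self):
        # removing C from ((A:1,B:2):5,C:3) leaves {A,B} spanning 1+2 = 3
        tree = parse_newick("((A:1,B:2):5,C:3);")
        assert unique_contribution(tree, "C", "unrooted") == (1 + 2 + 5 + 3) - 3.0

    def test_zero_pendant_contributes_zero(self):
        tree = parse_newick("((A:0,B:2):1,C:3);")
        assert unique_contribution(tree, "A", "rooted") == 0.0
        assert unique_contribution(tree, "A", "unrooted") == 0.0

    @given(seed=st.integers(0, 2000), n=st.integers(3, 15))
    @settings(max_examples=40, deadline=None)
    def test_sum_of_contributions_bounded_by_total(self, seed, n):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed))
        labels = write_leaf_list(tree)
        for mode in ("rooted", "unrooted"):
            s = sum(unique_contribution(tree, t, mode) for t in labels)
            assert s <= pd(tree, set(labels), mode) + 1e-9


class TestGreedy:
    def test_worked_selection(self, four_leaf_tree):
        result = greedy_select(four_leaf_tree, k=2)
        assert [(s.taxon, s.marginal_gain, s.cumulative_pd) for s in result.steps] == [
            ("C", 5.0, 5.0),
            ("B", 3.0, 8.0),
        ]

    def test_preselected_baseline(self, four_leaf_tree):
        result = greedy_select(four_leaf_tree, k=1, preselected={"C"})
        assert result.preselected_pd == 5.0
        assert [(s.taxon, s.marginal_gain, s.cumulative_pd) for s in result.steps] == [
            ("B", 3.0, 8.0)
        ]

    def test_exhaustion_reaches_total(self, four_leaf_tree):
        result = greedy_select(four_leaf_tree, k=4)
        assert result.final_pd == total_branch_length(four_leaf_tree)

    def test_pool_errors(self, four_leaf_tree):
        with pytest.raises(SelectionError, match="eligible pool"):
            greedy_select(four_leaf_tree, k=3, excluded={"A", "B"})
        with pytest.raises(SelectionError, match="overlap"):
            greedy_select(four_leaf_tree, k=1, preselected={"A"}, excluded={"A"})

    def test_unrooted_first_pick_is_lexicographic(self, four_leaf_tree):
        result = greedy_select(four_leaf_tree, k=2, mode="unrooted")
        assert result.steps[0].taxon == "A"
        assert result.steps[0].marginal_gain == 0.0

    @given(seed=st.integers(0, 3000), n=st.integers(4, 18), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_gains_non_increasing_and_cumulative_consistent(self, seed, n, data):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed))
        labels = write_leaf_list(tree)
        pre = set(data.draw(st.lists(st.sampled_from(labels), max_size=n // 3)))
        mode = data.draw(st.sampled_from(["rooted", "unrooted"]))
        k = len(labels) - len(pre)
        result = greedy_select(tree, k=k, preselected=pre, mode=mode)
        cum = result.preselected_pd
        prev = math.inf
        for i, step in enumerate(result.steps):
            if not (mode == "unrooted" and not pre and i == 1):
                # submodular non-increase; the one exception is the unrooted
                # seed step, whose gain is identically 0 before any tree exists
                assert step.marginal_gain <= prev + 1e-9
            cum += step.marginal_gain
            assert math.isclose(cum, step.cumulative_pd, rel_tol=1e-12, abs_tol=1e-12)
            prev = step.marginal_gain
        assert math.isclose(result.final_pd, pd(tree, set(labels), mode), rel_tol=1e-9)


class TestBruteForce:
    def test_worked_example(self, four_leaf_tree):
        best, value = brute_force_select(four_leaf_tree, k=2)
        assert best == {"B", "C"}
        assert value == 8.0

    def test_k_zero(self, four_leaf_tree):
        best, value = brute_force_select(four_leaf_tree, k=0, preselected={"C"})
        assert best == frozenset()
        assert value == 5.0

    def test_star_tie_break_lexicographic(self):
        tree = parse_newick(star_newick(5))
        best, _ = brute_force_select(tree, k=2)
        assert best == {"L000", "L001"}

    def test_refuses_large_pools(self):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=25, seed=0))
        with pytest.raises(OracleRefusalError, match="20"):
            brute_force_select(tree, k=2)


class TestCoverage:
    def test_worked_fractions(self, four_leaf_tree):
        report = pd_coverage(four_leaf_tree, {"seq": {"C"}, "seq+proposed": {"C", "B"}})
        assert report.fraction("seq") == 0.5
        assert report.fraction("seq+proposed") == 0.8

    def test_full_set_fraction_is_one(self, four_leaf_tree):
        report = pd_coverage(four_leaf_tree, {"all": {"A", "B", "C", "D"}})
        assert report.fraction("all") == 1.0

    @given(seed=st.integers(0, 2000), n=st.integers(3, 15), scale=st.floats(0.01, 1000))
    @settings(max_examples=40, deadline=None)
    def test_fractions_invariant_under_rescaling(self, seed, n, scale):
        tree = simulate_yule_tree(SimulationSpec(n_leaves=n, seed=seed))
        labels = write_leaf_list(tree)
        subset = set(labels[: n // 2])
        base = pd_coverage(tree, {"s": subset}).fraction("s")
        scaled = tree.__class__(
            parent=tree.parent,
            branch_length=[b * scale for b in tree.branch_length],
            children=tree.children,
            leaf_label=tree.leaf_label,
        )
        assert math.isclose(pd_coverage(scaled, {"s": subset}).fraction("s"), base, rel_tol=1e-9)
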