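"""Clanistics: support collapsing, p-score, E*, classification, modules."""

import math

import numpy as np
import pytest

from _oracles import (
    brute_force_p_score,
    enumerate_classification,
    native_groups_by_enumeration,
)
from pqclan import simulate
from pqclan.clanistics import (
    classify_tree,
    e_star,
    find_mobile_modules,
    forest_summary,
    label_tree,
    native_group_sizes,
    p_score,
    percentage,
)
from pqclan.trees import collapse_low_support, parse_newick


def random_labels(tree, rng, p_native=0.5):
    return {leaf for leaf in tree.leaves if rng.random() < p_native}


class TestCollapseLowSupport:
    def test_weak_edge_contracted(self):
        tree = parse_newick("((A,B)40,(C,D));")
        collapsed = collapse_low_support(tree, 50)
        assert len(collapsed.internal_edges()) == 0
        assert sorted(collapsed.leaves) == ["A", "B", "C", "D"]

    def test_strong_topology_unchanged(self):
        tree = parse_newick("((A,B)80,((C,D)95,E)70,F);")
        collapsed = collapse_low_support(tree, 50)
        assert collapsed.bipartitions() == tree.bipartitions()

    def test_unsupported_edges_kept(self):
        tree = parse_newick("((A,B),(C,D));")
        assert len(collapse_low_support(tree, 50).internal_edges()) == 1

    def test_alternating_caterpillar_keeps_one_edge(self):
        # 6-leaf caterpillar, internal edge supports 30, 90, 30
        tree = parse_newick("(A,B,(C,(D,(E,F)30)90)30);")
        collapsed = collapse_low_support(tree, 50)
        assert len(collapsed.internal_edges()) == 1
        assert collapsed.n_leaves == 6

    def test_cutoff_out_of_range(self):
        with pytest.raises(ValueError):
            collapse_low_support(parse_newick("(A,B,(C,D));"), 150)


class TestPScore:
    def test_all_native_is_zero(self):
        tree = parse_newick("(A,B,(C,D));")
        assert p_score(label_tree(tree, tree.leaves)) == 0

    def test_single_clan_costs_one(self):
        tree = parse_newick("((E1,E2),(B1,B2));")
        assert p_score(label_tree(tree, ["E1", "E2"])) == 1

    def test_matches_brute_force_on_random_trees(self, random_tree_factory):
        rng = np.random.default_rng(42)
        for seed in range(25):
            tree = random_tree_factory(int(rng.integers(4, 11)), seed)
            natives = random_labels(tree, rng)
            labeled = label_tree(tree, natives)
            assert p_score(labeled) == brute_force_p_score(tree, natives)

    def test_label_symmetric(self, random_tree_factory):
        rng = np.random.default_rng(7)
        for seed in range(10):
            tree = random_tree_factory(8, seed)
            natives = random_labels(tree, rng)
            intruders = set(tree.leaves) - natives
            assert p_score(label_tree(tree, natives)) == p_score(
                label_tree(tree, intruders)
            )

    def test_collapsing_agrees_with_oracle_and_never_lowers_score(
        self, random_tree_factory
    ):
        rng = np.random.default_rng(11)
        for seed in range(10):
            tree = random_tree_factory(9, seed)
            for u, v in tree.internal_edges():
                tree.graph.edges[u, v]["support"] = float(rng.integers(0, 101))
            natives = random_labels(tree, rng)
            collapsed = collapse_low_support(tree, 50)
            before = p_score(label_tree(tree, natives))
            after = p_score(label_tree(collapsed, natives))
            assert before == brute_force_p_score(tree, natives)
            assert after == brute_force_p_score(collapsed, natives)
            assert after >= before  # contraction restricts the assignments


class TestEStar:
    def test_single_clan_is_zero(self):
        tree = parse_newick("((E1,E2),(B1,B2));")
        assert e_star(label_tree(tree, ["E1", "E2"])) == 0.0

    def test_full_alternation_is_one(self):
        # caterpillar with natives and intruders strictly alternating
        tree = parse_newick("(E1,B1,(E2,(B2,(E3,B3))));")
        assert e_star(label_tree(tree, ["E1", "E2", "E3"])) == pytest.approx(1.0)

    def test_two_equal_groups_is_half(self):
        # 8 leaves, native groups of sizes {2, 2}
        tree = parse_newick("((E1,E2),(B1,B2),((E3,E4),(B3,B4)));")
        labeled = label_tree(tree, ["E1", "E2", "E3", "E4"])
        assert sorted(native_group_sizes(labeled)) == [2, 2]
        assert e_star(labeled) == pytest.approx(
            -2 * (0.5 * math.log(0.5)) / math.log(4)
        )
        assert e_star(labeled) == pytest.approx(0.5)

    def test_no_natives_is_undefined(self):
        tree = parse_newick("(B1,B2,(B3,B4));")
        assert e_star(label_tree(tree, [])) is None

    def test_groups_match_enumeration_and_bounds(self, random_tree_factory):
        rng = np.random.default_rng(3)
        for seed in range(20):
            tree = random_tree_factory(int(rng.integers(4, 12)), seed)
            natives = random_labels(tree, rng)
            if not natives:
                continue
            labeled = label_tree(tree, natives)
            assert sorted(native_group_sizes(labeled)) == \
                native_groups_by_enumeration(tree, natives)
            value = e_star(labeled)
            assert 0.0 <= value <= 1.0


class TestClassification:
    def test_pure(self):
        tree = parse_newick("(A,B,(C,D));")
        report = classify_tree(label_tree(tree, tree.leaves))
        assert report.classification == "pure"
        assert report.e_star == 0.0 and report.p_score == 0

    def test_perfect_clan(self):
        tree = parse_newick("((E1,E2),(B1,B2));")
        report = classify_tree(label_tree(tree, ["E1", "E2"]))
        assert report.classification == "perfect_clan"
        assert report.p_score == 1 and report.e_star == 0.0

    def test_perfect_slice_on_caterpillar(self):
        # natives contiguous in the middle, intruders on both ends
        tree = parse_newick("(B1,E1,(E2,B2));")
        report = classify_tree(label_tree(tree, ["E1", "E2"]))
        assert report.classification == "perfect_slice"
        assert report.p_score == 2

    def test_trivial_single_native_flagged(self):
        tree = parse_newick("(E1,B1,(B2,B3));")
        report = classify_tree(label_tree(tree, ["E1"]))
        assert report.classification == "perfect_clan"
        assert report.trivial

    def test_matches_cut_enumeration_on_random_trees(self, random_tree_factory):
        rng = np.random.default_rng(5)
        checked = set()
        for seed in range(40):
            tree = random_tree_factory(int(rng.integers(4, 10)), seed)
            natives = random_labels(tree, rng)
            got = classify_tree(label_tree(tree, natives)).classification
            assert got == enumerate_classification(tree, natives)
            checked.add(got)
        assert "melange" in checked and "perfect_clan" in checked

    def test_classification_consistent_with_p_score(self, random_tree_factory):
        rng = np.random.default_rng(9)
        for seed in range(30):
            tree = random_tree_factory(8, seed)
            report = classify_tree(label_tree(tree, random_labels(tree, rng)))
            if report.classification == "pure":
                assert report.p_score == 0
            elif report.classification == "perfect_clan":
                assert report.p_score == 1
                assert report.e_star == 0.0
            elif report.classification == "perfect_slice":
                assert report.p_score == 2


class TestForestSummary:
    def test_counts_and_percentages_on_toy_forest(self):
        config = simulate.SimulationConfig(n_strains=8, n_trees=25, seed=4)
        forest, annotations, _ = simulate.simulate_forest(config)
        summary = forest_summary(forest, annotations, "ecoli")
        assert summary.n_trees == 25
        assert sum(summary.counts.values()) == 25
        for cls, count in summary.counts.items():
            assert summary.percentages[cls] == percentage([count], 25)

    def test_empty_forest_all_zero(self):
        config = simulate.SimulationConfig(n_strains=8, n_trees=1, seed=0)
        _, annotations, _ = simulate.simulate_forest(config)
        summary = forest_summary([], annotations, "ecoli")
        assert summary.n_trees == 0
        assert all(v == 0 for v in summary.counts.values())

    def test_support_collapse_changes_are_consistent(self):
        config = simulate.SimulationConfig(n_strains=8, n_trees=15, seed=6)
        forest, annotations, _ = simulate.simulate_forest(config)
        raw = forest_summary(forest, annotations, "path")
        strict = forest_summary(forest, annotations, "path", support_cutoff=50)
        assert raw.n_trees == strict.n_trees


class TestMobileModules:
    def test_planted_modules_recovered(self):
        config = simulate.SimulationConfig(
            n_strains=12, n_trees=50, seed=8, planted_modules=(2, 2, 3)
        )
        forest, annotations, truth = simulate.simulate_forest(config)
        groups = find_mobile_modules(forest, annotations)
        by_tree = {tid: tt for tid, tt in truth.trees.items()}
        # every planted module id appears as (a subset of) one recovered group
        planted = {}
        for tid, tt in by_tree.items():
            if tt.module_id:
                planted.setdefault(tt.module_id, set()).add(tid)
        recovered = [set(g) for g in groups]
        for module_trees in planted.values():
            assert any(module_trees <= g for g in recovered)
        # and recovery matches an independent brute force over the outputs
        expected = {}
        strains = set(annotations.strains())
        for tree in forest:
            recs = [annotations[leaf] for leaf in tree.leaves]
            if not any(r.taxon_class == "MGE" for r in recs):
                continue
            lifestyles = {r.pathogenicity for r in recs if r.pathogenicity != "OTH"}
            if lifestyles != {"PATH"}:
                continue
            key = frozenset(r.genome_id for r in recs if r.genome_id in strains)
            expected.setdefault(key, set()).add(tree.tree_id)
        expected_groups = sorted(
            sorted(g) for g in expected.values() if len(g) >= 2
        )
        assert sorted(groups) == expected_groups

    def test_tree_with_nonpath_leaf_excluded(self):
        config = simulate.SimulationConfig(n_strains=8, n_trees=30, seed=2)
        forest, annotations, _ = simulate.simulate_forest(config)
        for group in find_mobile_modules(forest, annotations):
            for tid in group:
                tree = next(t for t in forest if t.tree_id == tid)
                lifestyles = {
                    annotations[leaf].pathogenicity for leaf in tree.leaves
                }
                assert "NON-PATH" not in lifestyles
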