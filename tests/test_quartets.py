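"""Polychromatic quartets: topology induction, sampling, matrix, Mantel."""

import numpy as np
import pytest

from _oracles import exhaustive_quartet_frequencies
from pqclan import simulate
from pqclan.io import DistanceMatrix, ValidationError
from pqclan.quartets import (
    assemble_matrix,
    compare_mean_distances,
    induced_quartet_topology,
    mantel_test,
    partition_forest,
    pq_distance,
    sample_pqs,
)
from pqclan.trees import parse_newick


def strain_map_for(annotations):
    return {
        seq: rec.genome_id
        for seq, rec in annotations.items()
        if rec.taxon_class.startswith("EC")
    }


class TestInducedQuartetTopology:
    def test_supported_split(self):
        tree = parse_newick("((A,B)90,(C,D));")
        split = induced_quartet_topology(tree, ["A", "B", "C", "D"], 50)
        assert {frozenset(p) for p in split} == {
            frozenset(("A", "B")), frozenset(("C", "D"))
        }

    def test_cutoff_above_support_unresolved(self):
        tree = parse_newick("((A,B)90,(C,D));")
        assert induced_quartet_topology(tree, ["A", "B", "C", "D"], 95) is None

    def test_star_unresolved(self):
        tree = parse_newick("(A,B,C,D);")
        assert induced_quartet_topology(tree, ["A", "B", "C", "D"], 50) is None

    def test_unsupported_edges_count_as_supported(self):
        tree = parse_newick("((A,B),(C,D));")
        assert induced_quartet_topology(tree, ["A", "B", "C", "D"], 50) is not None

    def test_missing_leaf_raises(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(KeyError):
            induced_quartet_topology(tree, ["A", "B", "C", "Z"], 50)

    def test_subquartet_of_larger_tree(self):
        tree = parse_newick("(((A,B)90,(C,D)85)95,(E,F)80);")
        split = induced_quartet_topology(tree, ["A", "C", "E", "F"], 50)
        assert {frozenset(p) for p in split} == {
            frozenset(("A", "C")), frozenset(("E", "F"))
        }


class TestSamplePqs:
    def test_four_strain_tree_gives_unit_frequencies(self):
        tree = parse_newick("((a1,b1)90,(c1,d1));")
        strain_of = {"a1": "EC1", "b1": "EC2", "c1": "EC3", "d1": "EC4"}
        tally = sample_pqs(tree, strain_of, n_quartets=50, rng=0)
        matrix = assemble_matrix([tally], ["EC1", "EC2", "EC3", "EC4"])
        freq = matrix.frequency
        strains = list(matrix.strains)
        same = {("EC1", "EC2"), ("EC3", "EC4")}
        for i in range(4):
            for j in range(i + 1, 4):
                expected = 1.0 if (strains[i], strains[j]) in same else 0.0
                assert freq[i, j] == expected

    def test_fewer_than_four_strains_skipped(self):
        tree = parse_newick("((a1,b1),(c1,a2));")
        strain_of = {"a1": "EC1", "b1": "EC2", "c1": "EC3", "a2": "EC1"}
        assert sample_pqs(tree, strain_of, 10, rng=0) is None

    def test_fixed_seed_reproducible(self):
        config = simulate.SimulationConfig(n_strains=8, n_trees=1, seed=3)
        forest, annotations, _ = simulate.simulate_forest(config)
        strain_of = strain_map_for(annotations)
        t1 = sample_pqs(forest[0], strain_of, 200, rng=7)
        t2 = sample_pqs(forest[0], strain_of, 200, rng=7)
        assert t1 == t2

    def test_sampled_frequencies_match_exhaustive_oracle(self):
        """Six-strain single-copy tree: sampled within 3 binomial SE of the
        exhaustive per-pair frequency over all 15 quartets."""
        tree = parse_newick(
            "((a,b),(c,(d,(e,f))));".replace("a", "s1|EC1")
            .replace("b", "s2|EC2").replace("c", "s3|EC3")
            .replace("d", "s4|EC4").replace("e", "s5|EC5")
            .replace("f", "s6|EC6")
        )
        strain_of = {f"s{i}|EC{i}": f"EC{i}" for i in range(1, 7)}
        oracle = exhaustive_quartet_frequencies(tree, strain_of)
        n = 1500
        tally = sample_pqs(tree, strain_of, n_quartets=n, rng=11)
        for (a, b), (same, cooc) in tally.items():
            f_exact = oracle[frozenset((a, b))]
            se = np.sqrt(f_exact * (1 - f_exact) / max(cooc, 1))
            assert abs(same / cooc - f_exact) <= max(3 * se, 1e-12)


class TestAssembleAndDistance:
    def test_thirty_strains_have_435_pair_slots(self):
        strains = [f"EC{i}" for i in range(1, 31)]
        tally = {("EC1", "EC2"): [3, 4]}
        matrix = assemble_matrix([tally], strains)
        assert matrix.n_pairs == 435

    def test_pooling_doubles_counts_keeps_frequencies(self):
        strains = ["EC1", "EC2", "EC3", "EC4"]
        tally = {("EC1", "EC2"): [3, 4], ("EC3", "EC4"): [1, 4]}
        one = assemble_matrix([tally], strains)
        two = assemble_matrix([tally, dict(tally)], strains)
        assert np.all(two.same_clan == 2 * one.same_clan)
        i, j = 0, 1
        assert two.frequency[i, j] == one.frequency[i, j]

    def test_pair_in_single_tree_keeps_its_frequency(self):
        strains = ["EC1", "EC2", "EC3", "EC4"]
        t1 = {("EC1", "EC2"): [2, 4]}
        t2 = {("EC3", "EC4"): [4, 4]}
        matrix = assemble_matrix([t1, t2], strains)
        assert matrix.frequency[0, 1] == 0.5
        assert matrix.frequency[2, 3] == 1.0

    def test_distance_is_one_complement(self):
        strains = ["EC1", "EC2", "EC3", "EC4"]
        tally = {("EC1", "EC2"): [4, 4], ("EC3", "EC4"): [0, 4]}
        dist = pq_distance(assemble_matrix([tally], strains))
        assert dist.get("EC1", "EC2") == 0.0
        assert dist.get("EC3", "EC4") == 1.0

    def test_never_cosampled_pairs_flagged_and_imputed(self):
        strains = ["EC1", "EC2", "EC3", "EC4"]
        tally = {("EC1", "EC2"): [2, 4]}
        matrix = assemble_matrix([tally], strains)
        assert frozenset(("EC3", "EC4")) in matrix.missing_pairs()
        dist = pq_distance(matrix, impute="mean")
        assert not dist.missing_mask
        assert dist.get("EC3", "EC4") == pytest.approx(0.5)  # matrix mean


class TestPartitionForest:
    def test_partition_matches_generator_truth(self):
        config = simulate.SimulationConfig(
            n_strains=10, n_trees=60, core_fraction=0.4, seed=13
        )
        forest, annotations, truth = simulate.simulate_forest(config)
        strain_of = strain_map_for(annotations)
        part = partition_forest(forest, strain_of, annotations.strains())
        expected_core = {t for t, tt in truth.trees.items() if tt.is_core}
        assert set(part.core) == expected_core
        assert set(part.shell) == set(truth.trees) - expected_core
        expected_single = {
            t for t, tt in truth.trees.items() if not tt.duplicated_strains
        }
        assert set(part.single_copy) == expected_single
        assert set(part.core) | set(part.shell) == set(truth.trees)
        assert not set(part.core) & set(part.shell)

    def test_duplicated_strain_is_shell_not_single_copy(self):
        tree = parse_newick("((a1,a2),(b1,(c1,d1)));")
        strain_of = {"a1": "EC1", "a2": "EC1", "b1": "EC2", "c1": "EC3",
                     "d1": "EC4"}
        part = partition_forest([tree], strain_of,
                                ["EC1", "EC2", "EC3", "EC4", "EC5"])
        assert part.shell == [tree.tree_id]
        assert part.single_copy == []


class TestMantel:
    def _dist(self, values, taxa=None):
        values = np.asarray(values, dtype=float)
        taxa = taxa or [f"EC{i}" for i in range(1, len(values) + 1)]
        return DistanceMatrix(tuple(taxa), values)

    def test_perfect_design_correlation(self):
        groups = {"EC1": "PATH", "EC2": "PATH", "EC3": "NON-PATH",
                  "EC4": "NON-PATH"}
        design = np.array([
            [0, 0, 1, 1.0],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ])
        r, p = mantel_test(self._dist(design), groups, n_permutations=999, rng=0)
        assert r == pytest.approx(1.0)
        # 2 of 6 relabelings of 2+2 taxa reproduce the same partition
        assert p == pytest.approx(1 / 3, abs=0.07)

    def test_fixed_seed_reproducible(self, rng):
        n = 10
        vals = rng.uniform(0, 1, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        groups = {f"EC{i}": ("PATH" if i <= 6 else "NON-PATH")
                  for i in range(1, n + 1)}
        d = self._dist(vals)
        assert mantel_test(d, groups, 999, rng=5) == mantel_test(d, groups, 999,
                                                                 rng=5)

    def test_constant_matrix_rejected(self):
        vals = np.ones((4, 4)) - np.eye(4)
        vals[vals == 1] = 0.5
        groups = {"EC1": "PATH", "EC2": "PATH", "EC3": "NON-PATH",
                  "EC4": "NON-PATH"}
        with pytest.raises(ValidationError):
            mantel_test(self._dist(vals), groups, 99, rng=0)

    def test_matches_scikit_bio_oracle(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        n = 12
        vals = rng.uniform(0, 1, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        taxa = [f"EC{i}" for i in range(1, n + 1)]
        groups = {t: ("PATH" if i < 8 else "NON-PATH")
                  for i, t in enumerate(taxa)}
        labels = np.array([groups[t] for t in taxa])
        design = (labels[:, None] != labels[None, :]).astype(float)
        r_ours, p_ours = mantel_test(self._dist(vals, taxa), groups,
                                     n_permutations=999, rng=1)
        r_ref, p_ref, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(vals, ids=taxa),
            skbio_stats.DistanceMatrix(design, ids=taxa),
            method="pearson", permutations=999, alternative="greater",
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-10)
        assert p_ours == pytest.approx(float(p_ref), abs=0.05)


class TestCoreVsShell:
    def test_welch_test_detects_shifted_distances(self, rng):
        n = 10
        base = rng.uniform(0.2, 0.4, size=(n, n))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        taxa = tuple(f"EC{i}" for i in range(1, n + 1))
        shifted = np.clip(base + 0.3, 0, 1)
        np.fill_diagonal(shifted, 0)
        t, p = compare_mean_distances(
            DistanceMatrix(taxa, base), DistanceMatrix(taxa, shifted)
        )
        assert t < 0 and p < 1e-6
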