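"""Polychromatic quartets (PQ): quartet-based dissection of a gene forest.

For each gene tree, quartets of four distinct strains are sampled; the
bipartition induced by the tree (when bootstrap-supported) contributes one
"same clan" observation for each of the two within-pair strain pairs and a
co-occurrence observation for all six pairs of the quartet.  Pooled over the
forest, the per-pair same-clan frequency measures how consistently two
strains group together; its one-complement is a distance suitable for
split-network analysis, and a Mantel permutation test on that distance
matrix probes group-structured lateral transfer (e.g. pathogens exchanging
genes preferentially with pathogens).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import DistanceMatrix, ValidationError
from .trees import GeneTree, PathTable

PairTally = dict[tuple[str, str], list]  # (strain_a < strain_b) -> [same, cooc]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def induced_quartet_topology(
    tree: GeneTree,
    leaves: Sequence[str],
    support_cutoff: float = 50.0,
    path_table: PathTable | None = None,
) -> tuple[tuple[str, str], tuple[str, str]] | None:
    """Bipartition of four leaves induced by the tree, or ``None``.

    Returns the two cherries of the induced quartet provided the internal
    path separating them contains at least one edge with support >=
    ``support_cutoff`` (edges without a recorded support count as
    supported); returns ``None`` for star quartets or failing support.
    """
    a, b, c, d = leaves
    for leaf in leaves:
        if leaf not in tree.graph:
            raise KeyError(f"leaf {leaf!r} not in tree {tree.tree_id}")
    pt = path_table if path_table is not None else PathTable(tree)
    dab, dcd = pt.dist(a, b), pt.dist(c, d)
    dac, dbd = pt.dist(a, c), pt.dist(b, d)
    dad, dbc = pt.dist(a, d), pt.dist(b, c)
    sums = {
        ((a, b), (c, d)): dab + dcd,
        ((a, c), (b, d)): dac + dbd,
        ((a, d), (b, c)): dad + dbc,
    }
    ranked = sorted(sums.items(), key=lambda kv: kv[1])
    if ranked[0][1] == ranked[1][1]:
        return None  # star: no strict minimum
    (p1, p2), _ = ranked[0]
    # middle path = intersection of the two cross paths
    middle = pt.edges(p1[0], p2[0]) & pt.edges(p1[1], p2[1])
    if not middle:
        return None
    g = tree.graph
    for edge in middle:
        u, v = tuple(edge)
        sup = g.edges[u, v].get("support")
        if sup is None or sup >= support_cutoff:
            return (p1, p2)
    return None


def strain_leaf_map(
    strain_of: Mapping[str, str], leaves: Iterable[str]
) -> dict[str, list[str]]:
    """Group a tree's leaves by strain, ignoring non-strain leaves."""
    out: dict[str, list[str]] = {}
    for leaf in leaves:
        strain = strain_of.get(leaf)
        if strain is not None:
            out.setdefault(strain, []).append(leaf)
    for copies in out.values():
        copies.sort()
    return out


def sample_pqs(
    tree: GeneTree,
    strain_of: Mapping[str, str],
    n_quartets: int = 1000,
    support_cutoff: float = 50.0,
    rng: np.random.Generator | int | None = None,
) -> PairTally | None:
    """Sample strain quartets from one tree and tally clan membership.

    Per draw: four distinct strains are chosen uniformly; for a strain with
    several leaf copies one copy is drawn uniformly; the induced quartet
    topology is resolved.  A resolved quartet increments the co-occurrence
    count of all six strain pairs and the same-clan count of the two
    within-cherry pairs; an unresolved quartet increments nothing.  Returns
    ``None`` (tree skipped) when fewer than four strains are present.
    """
    rng = np.random.default_rng(rng)
    by_strain = strain_leaf_map(strain_of, tree.leaves)
    strains = sorted(by_strain)
    if len(strains) < 4:
        return None
    pt = PathTable(tree)
    tally: PairTally = {}
    n_strains = len(strains)
    for _ in range(n_quartets):
        idx = rng.choice(n_strains, size=4, replace=False)
        chosen = [strains[i] for i in idx]
        leaves = []
        for strain in chosen:
            copies = by_strain[strain]
            leaf = copies[rng.integers(len(copies))] if len(copies) > 1 else copies[0]
            leaves.append(leaf)
        split = induced_quartet_topology(tree, leaves, support_cutoff, pt)
        if split is None:
            continue
        leaf_strain = dict(zip(leaves, chosen))
        for s1, s2 in itertools.combinations(sorted(chosen), 2):
            tally.setdefault((s1, s2), [0, 0])[1] += 1
        for cherry in split:
            s1, s2 = leaf_strain[cherry[0]], leaf_strain[cherry[1]]
            tally[_pair(s1, s2)][0] += 1
    return tally


def exhaustive_pqs(
    tree: GeneTree,
    strain_of: Mapping[str, str],
    support_cutoff: float = 50.0,
) -> PairTally | None:
    """Enumerate every strain quartet (and every copy combination) once.

    Multi-copy strains contribute each copy combination with equal weight so
    that totals per quartet sum to one; counts are therefore fractional for
    multi-copy trees.  Used as the sampling-free reference.
    """
    by_strain = strain_leaf_map(strain_of, tree.leaves)
    strains = sorted(by_strain)
    if len(strains) < 4:
        return None
    pt = PathTable(tree)
    tally: PairTally = {}
    for chosen in itertools.combinations(strains, 4):
        combos = list(itertools.product(*(by_strain[s] for s in chosen)))
        weight = 1.0 / len(combos)
        for leaves in combos:
            split = induced_quartet_topology(tree, list(leaves), support_cutoff, pt)
            if split is None:
                continue
            leaf_strain = dict(zip(leaves, chosen))
            for s1, s2 in itertools.combinations(sorted(chosen), 2):
                tally.setdefault((s1, s2), [0.0, 0.0])[1] += weight
            for cherry in split:
                s1, s2 = leaf_strain[cherry[0]], leaf_strain[cherry[1]]
                tally[_pair(s1, s2)][0] += weight
    return tally


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class PQMatrix:
    """Pooled per-strain-pair quartet tallies."""

    strains: tuple[str, ...]
    same_clan: np.ndarray  # symmetric counts
    cooccurrence: np.ndarray

    @property
    def n_pairs(self) -> int:
        n = len(self.strains)
        return n * (n - 1) // 2

    @property
    def frequency(self) -> np.ndarray:
        """same_clan / cooccurrence, NaN where never co-sampled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(
                self.cooccurrence > 0, self.same_clan / np.where(
                    self.cooccurrence > 0, self.cooccurrence, 1
                ), np.nan
            )
        np.fill_diagonal(freq, np.nan)
        return freq

    def missing_pairs(self) -> set[frozenset]:
        out = set()
        n = len(self.strains)
        for i in range(n):
            for j in range(i + 1, n):
                if self.cooccurrence[i, j] == 0:
                    out.add(frozenset((self.strains[i], self.strains[j])))
        return out


def assemble_matrix(
    tallies: Iterable[PairTally | None], strains: Sequence[str]
) -> PQMatrix:
    """Pool per-tree tallies by summing counts over the forest."""
    strains = tuple(strains)
    index = {s: i for i, s in enumerate(strains)}
    n = len(strains)
    same = np.zeros((n, n))
    cooc = np.zeros((n, n))
    n_used = 0
    for tally in tallies:
        if tally is None:
            continue
        n_used += 1
        for (a, b), (s, c) in tally.items():
            i, j = index[a], index[b]
            same[i, j] += s
            same[j, i] += s
            cooc[i, j] += c
            cooc[j, i] += c
    if n_used == 0:
        raise ValidationError("no tallied trees to assemble")
    return PQMatrix(strains, same, cooc)


def pq_distance(matrix: PQMatrix, impute: str | None = "mean") -> DistanceMatrix:
    """One-complement of the same-clan frequency matrix.

    ``d(i, j) = 1 - frequency(i, j)`` with zero diagonal.  Pairs never
    co-sampled are imputed by the mean off-diagonal distance
    (``impute="mean"``, imputed pairs flagged in ``missing_mask`` cleared)
    or left missing (``impute=None``, recorded in ``missing_mask``).
    """
    freq = matrix.frequency
    d = 1.0 - freq
    np.fill_diagonal(d, 0.0)
    missing = matrix.missing_pairs()
    if np.all(np.isnan(d[np.triu_indices(len(matrix.strains), 1)])):
        raise ValidationError("all strain pairs missing; nothing to build")
    if impute == "mean":
        mean = float(np.nanmean(d[np.triu_indices(len(matrix.strains), 1)]))
        d = np.where(np.isnan(d), mean, d)
        return DistanceMatrix(matrix.strains, d, set())
    if impute is None:
        d = np.where(np.isnan(d), 0.0, d)
        return DistanceMatrix(matrix.strains, d, missing)
    raise ValueError(f"unknown impute option {impute!r}")


# ---------------------------------------------------------------------------
# forest partition


@dataclass
class ForestPartition:
    """Core/shell/single-copy membership of the PQ-eligible forest."""

    core: list[str] = field(default_factory=list)
    shell: list[str] = field(default_factory=list)
    single_copy: list[str] = field(default_factory=list)
    ineligible: list[str] = field(default_factory=list)


def partition_forest(
    forest: Iterable[GeneTree],
    strain_of: Mapping[str, str],
    all_strains: Sequence[str],
) -> ForestPartition:
    """Split a forest into core (all strains present), shell (fewer), and
    single-copy (at most one leaf per strain) trees; PQ-eligible trees carry
    at least four distinct strains."""
    all_strains = set(all_strains)
    part = ForestPartition()
    for tree in forest:
        by_strain = strain_leaf_map(strain_of, tree.leaves)
        if len(by_strain) < 4:
            part.ineligible.append(tree.tree_id)
            continue
        if set(by_strain) == all_strains:
            part.core.append(tree.tree_id)
        else:
            part.shell.append(tree.tree_id)
        if all(len(copies) <= 1 for copies in by_strain.values()):
            part.single_copy.append(tree.tree_id)
    return part


# ---------------------------------------------------------------------------
# statistics


def mantel_test(
    dist: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 9999,
    rng: np.random.Generator | int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel permutation test of distances against a group design matrix.

    ``r`` is the Pearson correlation between off-diagonal distances and the
    binary design (0 within group, 1 between groups); ``p`` the one-tailed
    permutation p-value over random relabelings of the taxa, testing whether
    between-group distances exceed within-group ones.
    """
    if dist.missing_mask:
        raise ValidationError("distance matrix has missing pairs")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(rng)
    labels = np.array([groups[t] for t in dist.taxa])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) != 2 or counts.min() < 2:
        raise ValidationError("need exactly two groups with >= 2 taxa each")
    iu = np.triu_indices(dist.n, k=1)
    x = dist.values[iu]
    if np.ptp(x) == 0:
        raise ValidationError("constant distance matrix; r undefined")

    x = (x - x.mean()) / x.std()

    def corr(lab: np.ndarray) -> float:
        design = (lab[:, None] != lab[None, :])[iu].astype(float)
        design = (design - design.mean()) / design.std()
        return float(np.mean(x * design))

    r_obs = corr(labels)
    hits = 0
    for _ in range(n_permutations):
        r_perm = corr(rng.permutation(labels))
        if alternative == "greater":
            hits += r_perm >= r_obs
        elif alternative == "less":
            hits += r_perm <= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p = (1 + hits) / (1 + n_permutations)
    return r_obs, p


def compare_mean_distances(
    a: DistanceMatrix, b: DistanceMatrix
) -> tuple[float, float]:
    """Welch two-sample t-test on the condensed pairwise distances.

    Caveat: the 435-style pair distances are not independent observations,
    so the p-value is indicative only.
    """
    t, p = sps.ttest_ind(a.condensed(), b.condensed(), equal_var=False)
    return float(t), float(p)


def write_matrix_tables(matrix: PQMatrix, counts_path, freq_path) -> None:
    """TSV export of pooled counts and frequencies."""
    strains = matrix.strains
    freq = matrix.frequency
    with open(counts_path, "w") as fh:
        fh.write("strain_a\tstrain_b\tsame_clan\tcooccurrence\n")
        for i, a in enumerate(strains):
            for j in range(i + 1, len(strains)):
                fh.write(
                    f"{a}\t{strains[j]}\t{matrix.same_clan[i, j]:g}"
                    f"\t{matrix.cooccurrence[i, j]:g}\n"
                )
    with open(freq_path, "w") as fh:
        fh.write("strain_a\tstrain_b\tfrequency\n")
        for i, a in enumerate(strains):
            for j in range(i + 1, len(strains)):
                val = freq[i, j]
                fh.write(f"{a}\t{strains[j]}\t{'' if np.isnan(val) else f'{val:.6f}'}\n")
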