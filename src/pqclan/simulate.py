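"""Synthetic forests, annotations and homology hits with known ground truth.

The generator emulates the data regime of a 30-strain bacterial pangenome
study: a forest of gene trees over in-group strains plus out-group taxa and
mobile-element leaves, with core/shell family structure, a tunable rate of
lateral transfer events (optionally biased towards same-lifestyle
donor/recipient pairs), bootstrap supports, and tabular homology hits with
controlled identity bands.  It is scaffolding for testing: the transfer
model (a recipient leaf pruned and regrafted next to its donor) captures the
topological signature of a gene replacement, not sequence evolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import AnnotationRecord, AnnotationTable, HomologyHit
from .trees import GeneTree, relabel_leaves, restrict


@dataclass(frozen=True)
class LgtEvent:
    donor: str
    recipient: str
    mge_attached: bool


@dataclass
class TreeTruth:
    tree_id: str
    strains_present: frozenset
    is_core: bool
    events: list[LgtEvent] = field(default_factory=list)
    duplicated_strains: list[str] = field(default_factory=list)
    module_id: str | None = None


@dataclass
class TruthTable:
    species_tree: GeneTree
    trees: dict[str, TreeTruth] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for forest simulation.

    Defaults mirror the regime the toolkit targets: 30 in-group strains of
    which two thirds are pathogenic, a core fraction of 0.4, a mean of two
    transfer events per gene tree (heavy-mixing regime), high supports
    (90-100) on species-tree-concordant edges and mixed supports (20-100) on
    edges created by transfer or duplication.
    """

    n_strains: int = 30
    n_outgroups: int = 4
    n_mge: int = 5
    n_trees: int = 100
    core_fraction: float = 0.4
    lgt_rate: float = 2.0
    within_group_bias: float = 1.0
    path_fraction: float = 2 / 3
    mge_event_fraction: float = 0.1
    duplication_rate: float = 0.1
    support_concordant: tuple[float, float] = (90.0, 100.0)
    support_discordant: tuple[float, float] = (20.0, 100.0)
    planted_modules: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 4 <= self.n_strains <= 30:
            raise ValueError("n_strains must be in [4, 30] (EC1..EC30 vocabulary)")
        if self.n_trees < 1:
            raise ValueError("need at least 1 tree")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.lgt_rate < 0 or self.within_group_bias < 1.0:
            raise ValueError("lgt_rate >= 0 and within_group_bias >= 1 required")
        if any(n < 0 for n in (self.n_outgroups, self.n_mge)):
            raise ValueError("counts must be non-negative")
        if any(size < 2 for size in self.planted_modules):
            raise ValueError("planted module sizes must be >= 2")


# ---------------------------------------------------------------------------
# tree construction helpers


def random_unrooted_tree(
    leaf_names: Sequence[str], rng: np.random.Generator
) -> GeneTree:
    """Random topology by Yule-style tip splitting (uniform tip choice)."""
    names = list(leaf_names)
    g = nx.Graph()
    if len(names) < 2:
        g.add_nodes_from(names)
        return GeneTree(g)
    if len(names) == 2:
        g.add_edge(names[0], names[1], support=None)
        return GeneTree(g)
    counter = itertools.count()
    root = next(counter)
    for name in names[:3]:
        g.add_edge(root, name, support=None)
    tips = list(names[:3])
    for name in names[3:]:
        tip = tips[rng.integers(len(tips))]
        (anchor,) = g[tip]
        new = next(counter)
        g.remove_edge(anchor, tip)
        g.add_edge(anchor, new, support=None)
        g.add_edge(new, tip, support=None)
        g.add_edge(new, name, support=None)
        tips.append(name)
    return GeneTree(g)


def _attach_leaf_adjacent(
    tree: GeneTree, target_leaf: str, new_leaf: str, new_node_ids: set
) -> None:
    """Graft ``new_leaf`` onto the pendant edge of ``target_leaf`` in place."""
    g = tree.graph
    (anchor,) = g[target_leaf]
    new_internal = max(
        (n for n in g.nodes if not isinstance(n, str)), default=-1
    ) + 1
    g.remove_edge(anchor, target_leaf)
    g.add_edge(anchor, new_internal, support=None)
    g.add_edge(new_internal, target_leaf, support=None)
    g.add_edge(new_internal, new_leaf, support=None)
    new_node_ids.add(new_internal)


def _assign_supports(
    tree: GeneTree, discordant_nodes: set, rng: np.random.Generator,
    concordant: tuple[float, float], discordant: tuple[float, float],
) -> None:
    for u, v in tree.internal_edges():
        band = discordant if (u in discordant_nodes or v in discordant_nodes) \
            else concordant
        tree.graph.edges[u, v]["support"] = float(
            np.round(rng.uniform(*band))
        )


# ---------------------------------------------------------------------------
# forest simulation


def simulate_forest(
    config: SimulationConfig,
) -> tuple[list[GeneTree], AnnotationTable, TruthTable]:
    """Generate a forest, its annotation table, and the ground truth.

    One fixed random species tree is drawn over strains and out-groups; each
    gene tree is its restriction to a sampled strain subset (core trees keep
    every strain), perturbed by Poisson(``lgt_rate``) transfer events whose
    donor/recipient strain pairs are up-weighted by ``within_group_bias``
    when both share a pathogenicity class.  A fraction of events deposits a
    mobile-element leaf next to the recipient.  Identical config and seed
    give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    strains = [f"EC{i}" for i in range(1, config.n_strains + 1)]
    outgroups = [f"OG{i}" for i in range(1, config.n_outgroups + 1)]
    n_path = int(round(config.path_fraction * config.n_strains))
    lifestyle = {
        s: ("PATH" if i < n_path else "NON-PATH") for i, s in enumerate(strains)
    }

    # species tree: strain subtree with an out-group clade on one edge
    if outgroups:
        strain_tree = random_unrooted_tree(strains + ["@og@"], rng)
        species = _splice_outgroups(strain_tree, outgroups, rng)
    else:
        species = random_unrooted_tree(strains, rng)
    species.tree_id = "species"

    pair_weights = _pair_weight_table(strains, lifestyle, config.within_group_bias)

    records: dict[str, AnnotationRecord] = {}
    truth = TruthTable(species_tree=species)
    forest: list[GeneTree] = []
    diseases = ("URI", "HEM", "GAS", "OTH")
    disease_of = {
        s: (diseases[rng.integers(len(diseases))] if lifestyle[s] == "PATH"
            else "none")
        for s in strains
    }

    def genome_record(genome: str, seq_id: str) -> None:
        if genome.startswith("EC"):
            records[seq_id] = AnnotationRecord(
                genome, genome, lifestyle[genome], disease_of[genome], "X"
            )
        elif genome.startswith("OG"):
            records[seq_id] = AnnotationRecord(genome, "BAC", "OTH", "none", "X")
        else:
            records[seq_id] = AnnotationRecord(genome, "MGE", "OTH", "none", "X")

    def build_tree(
        tree_id: str,
        subset: Sequence[str],
        include_outgroups: bool,
        module_id: str | None,
        force_mge: bool,
    ) -> None:
        keep = list(subset) + (outgroups if include_outgroups else [])
        gene = restrict(species, keep)
        gene.tree_id = tree_id
        mapping = {name: f"{tree_id}|{name}" for name in gene.leaves}
        gene = relabel_leaves(gene, mapping)
        gene.tree_id = tree_id
        leaf_of = {name: f"{tree_id}|{name}" for name in keep}
        tt = TreeTruth(
            tree_id,
            frozenset(subset),
            is_core=len(subset) == config.n_strains,
            module_id=module_id,
        )
        new_nodes: set = set()

        # lateral transfer events
        n_events = rng.poisson(config.lgt_rate)
        eligible = [p for p in pair_weights if p[0] in subset and p[1] in subset]
        if eligible and n_events:
            w = np.array([pair_weights[p] for p in eligible])
            w = w / w.sum()
            mge_counter = 0
            for _ in range(n_events):
                a, b = eligible[rng.choice(len(eligible), p=w)]
                donor, recipient = (a, b) if rng.random() < 0.5 else (b, a)
                attach_mge = force_mge or rng.random() < config.mge_event_fraction
                _transfer(gene, leaf_of[donor], leaf_of[recipient], new_nodes)
                if attach_mge:
                    mge_counter += 1
                    genome = f"MGE{1 + rng.integers(max(config.n_mge, 1))}"
                    mge_leaf = f"{tree_id}|{genome}.{mge_counter}"
                    _attach_leaf_adjacent(
                        gene, leaf_of[recipient], mge_leaf, new_nodes
                    )
                    genome_record(genome, mge_leaf)
                    force_mge = False
                tt.events.append(LgtEvent(donor, recipient, attach_mge))
        if force_mge:  # planted module trees always carry an MGE leaf
            genome = f"MGE{1 + rng.integers(max(config.n_mge, 1))}"
            mge_leaf = f"{tree_id}|{genome}.0"
            target = leaf_of[subset[int(rng.integers(len(subset)))]]
            _attach_leaf_adjacent(gene, target, mge_leaf, new_nodes)
            genome_record(genome, mge_leaf)

        # duplications (multi-copy strains)
        for _ in range(rng.poisson(config.duplication_rate)):
            strain = subset[int(rng.integers(len(subset)))]
            copy_leaf = f"{tree_id}|{strain}.dup"
            if copy_leaf in gene.graph:
                continue
            _attach_leaf_adjacent(gene, leaf_of[strain], copy_leaf, new_nodes)
            genome_record(strain, copy_leaf)
            tt.duplicated_strains.append(strain)

        _assign_supports(
            gene, new_nodes, rng, config.support_concordant,
            config.support_discordant,
        )
        for name in keep:
            genome_record(name, leaf_of[name])
        forest.append(gene)
        truth.trees[tree_id] = tt

    for t in range(config.n_trees):
        tree_id = f"g{t:04d}"
        if rng.random() < config.core_fraction:
            subset = strains
        else:
            size = int(rng.integers(4, config.n_strains)) \
                if config.n_strains > 4 else 4
            idx = rng.choice(config.n_strains, size=size, replace=False)
            subset = [strains[i] for i in sorted(idx)]
        build_tree(tree_id, subset, include_outgroups=True, module_id=None,
                   force_mge=False)

    # planted modules: groups of trees with identical all-pathogenic strain
    # vectors plus a mobile-element leaf
    path_strains = [s for s in strains if lifestyle[s] == "PATH"]
    for m, size in enumerate(config.planted_modules):
        k = int(rng.integers(4, max(len(path_strains), 5)))
        idx = rng.choice(len(path_strains), size=min(k, len(path_strains)),
                         replace=False)
        subset = [path_strains[i] for i in sorted(idx)]
        for j in range(size):
            build_tree(
                f"mod{m}_{j}", subset, include_outgroups=False,
                module_id=f"module{m}", force_mge=True,
            )

    return forest, AnnotationTable(records), truth


def _splice_outgroups(
    tree: GeneTree, outgroups: Sequence[str], rng: np.random.Generator
) -> GeneTree:
    """Replace the ``@og@`` placeholder leaf with an out-group clade."""
    g = tree.graph
    if len(outgroups) == 1:
        return GeneTree(nx.relabel_nodes(g, {"@og@": outgroups[0]}))
    og_tree = random_unrooted_tree(list(outgroups) + ["@anchor@"], rng)
    go = og_tree.graph
    offset = max((n for n in g.nodes if not isinstance(n, str)), default=-1) + 1
    mapping = {n: (n if isinstance(n, str) else n + offset) for n in go.nodes}
    (a_side,) = g["@og@"]
    (b_side,) = go["@anchor@"]
    joined = nx.Graph()
    joined.add_edges_from(g.edges(data=True))
    for u, v, data in go.edges(data=True):
        joined.add_edge(mapping[u], mapping[v], **data)
    joined.remove_node("@og@")
    joined.remove_node("@anchor@")
    joined.add_edge(a_side, mapping[b_side], support=None)
    return GeneTree(joined)


def _pair_weight_table(
    strains: Sequence[str], lifestyle: dict[str, str], bias: float
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(strains, 2):
        same = lifestyle[a] == lifestyle[b]
        out[(a, b)] = bias if same else 1.0
    return out


def _transfer(
    tree: GeneTree, donor_leaf: str, recipient_leaf: str, new_nodes: set
) -> None:
    """Prune the recipient leaf and regraft it next to the donor leaf."""
    g = tree.graph
    (anchor,) = g[recipient_leaf]
    g.remove_node(recipient_leaf)
    if not isinstance(anchor, str) and g.degree(anchor) == 2:
        u, v = g[anchor]
        g.remove_node(anchor)
        new_nodes.discard(anchor)
        if not g.has_edge(u, v):
            g.add_edge(u, v, support=None)
    g.add_node(recipient_leaf)
    _attach_leaf_adjacent(tree, donor_leaf, recipient_leaf, new_nodes)


# ---------------------------------------------------------------------------
# hit simulation


def simulate_hits(
    n_families: int,
    family_size_dist: Sequence[int] | None = None,
    identity_bands: Sequence[tuple[tuple[float, float], float]] = (
        ((70.0, 95.0), 0.8),
        ((100.0, 100.0), 0.2),
    ),
    seed: int = 0,
    genomes: Sequence[str] | None = None,
    evalue_max: float = 1e-20,
    n_spurious: int = 0,
) -> tuple[list[HomologyHit], AnnotationTable, dict[str, str]]:
    """Emit a homology-hit table with known family structure.

    Each family draws its size from ``family_size_dist`` (uniform choice
    over the listed sizes) and one identity band by the given probabilities;
    all within-family pairs receive hits in both directions with identities
    from the band and e-values below ``evalue_max``.  ``n_spurious``
    cross-family hit pairs with e-values above the threshold are added.
    Returns (hits, annotations, truth mapping sequence -> family id).
    """
    rng = np.random.default_rng(seed)
    if family_size_dist is None:
        family_size_dist = (2, 3, 4, 5)
    if genomes is None:
        genomes = tuple(f"EC{i}" for i in range(1, 6)) + ("MGE1", "MGE2")
    bands = [b for b, _ in identity_bands]
    probs = np.array([p for _, p in identity_bands], dtype=float)
    probs = probs / probs.sum()

    hits: list[HomologyHit] = []
    records: dict[str, AnnotationRecord] = {}
    truth: dict[str, str] = {}
    cogs = "LKXSTR"

    for f in range(n_families):
        fam_id = f"F{f:04d}"
        size = int(family_size_dist[rng.integers(len(family_size_dist))])
        lo, hi = bands[rng.choice(len(bands), p=probs)]
        cog = cogs[rng.integers(len(cogs))]
        members = []
        for k in range(size):
            seq = f"{fam_id}.s{k}"
            genome = genomes[rng.integers(len(genomes))]
            taxon = "MGE" if genome.startswith("MGE") else genome
            path = "OTH" if genome.startswith("MGE") else (
                "PATH" if genome in genomes[: len(genomes) // 2] else "NON-PATH"
            )
            records[seq] = AnnotationRecord(genome, taxon, path, "none", cog)
            truth[seq] = fam_id
            members.append(seq)
        for a, b in itertools.combinations(members, 2):
            ident = float(np.round(rng.uniform(lo, hi), 2))
            evalue = float(10.0 ** rng.uniform(-80, np.log10(evalue_max)))
            bitscore = float(np.round(100 + 5 * ident + rng.uniform(0, 10), 1))
            hits.append(HomologyHit(a, b, ident, 300, evalue, bitscore))
            hits.append(HomologyHit(b, a, ident, 300, evalue, bitscore))

    seqs = sorted(truth)
    for _ in range(n_spurious):
        a, b = (seqs[i] for i in rng.choice(len(seqs), size=2, replace=False))
        if truth[a] == truth[b]:
            continue
        ident = float(np.round(rng.uniform(25, 40), 2))
        evalue = float(10.0 ** rng.uniform(np.log10(evalue_max) + 2, -2))
        hits.append(HomologyHit(a, b, ident, 80, evalue, 30.0))

    return hits, AnnotationTable(records), truth
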