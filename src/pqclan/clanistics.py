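"""Clanistic harvesting of phylogenetic forests.

Leaves of each unrooted gene tree are split into *natives* (the category of
interest) and *intruders*.  A tree is *pure* when it has no intruders, a
*perfect clan* when one edge cut isolates exactly the natives, a *perfect
slice* when two cuts do and one cannot, and a *melange* otherwise.  Two
indices quantify the mixing: the p-score (two-state parsimony score of the
native/intruder character, equal to the minimum number of edge cuts
separating the categories) and E*, a Shannon equitability over the sizes of
the maximal all-native subtrees, normalized by ln(number of natives), so
that perfectly grouped natives score 0 and fully interleaved natives 1.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .io import AnnotationTable, ValidationError
from .trees import GeneTree, collapse_low_support, restrict, steiner_nodes

CLASSES = ("pure", "perfect_clan", "perfect_slice", "melange")


@dataclass(frozen=True)
class LabeledTree:
    """A gene tree with its leaves partitioned into natives and intruders."""

    tree: GeneTree
    native_set: frozenset
    intruder_set: frozenset

    def __post_init__(self):
        leaves = set(self.tree.leaves)
        if set(self.native_set) | set(self.intruder_set) != leaves:
            raise ValidationError("native and intruder sets must cover the leaves")
        if set(self.native_set) & set(self.intruder_set):
            raise ValidationError("native and intruder sets must be disjoint")


@dataclass(frozen=True)
class ClanReport:
    tree_id: str
    classification: str  # pure | perfect_clan | perfect_slice | melange | absent
    e_star: float | None
    p_score: int
    n_native: int
    n_intruder: int
    trivial: bool


def label_tree(
    tree: GeneTree, natives: Iterable[str]
) -> LabeledTree:
    natives = frozenset(natives)
    return LabeledTree(tree, natives, frozenset(tree.leaves) - natives)


# ---------------------------------------------------------------------------
# indices


def p_score(labeled: LabeledTree) -> int:
    """Two-state parsimony score of the native/intruder leaf character.

    Unit-cost Sankoff dynamic programme over the unrooted (possibly
    multifurcating) tree; equals the minimum number of edges that must be cut
    to separate every native leaf from every intruder leaf.
    """
    tree = labeled.tree
    g = tree.graph
    if g.number_of_nodes() <= 1 or not labeled.native_set or not labeled.intruder_set:
        return 0
    root = next(iter(g.nodes))
    INF = float("inf")
    cost: dict = {}
    # iterative post-order
    stack = [(root, None, False)]
    while stack:
        node, parent, expanded = stack.pop()
        if not expanded:
            stack.append((node, parent, True))
            for nb in g[node]:
                if nb != parent:
                    stack.append((nb, node, False))
        else:
            if isinstance(node, str):
                native = node in labeled.native_set
                cost[node] = (0 if native else INF, INF if native else 0)
            else:
                c0 = c1 = 0.0
                for nb in g[node]:
                    if nb == parent:
                        continue
                    k0, k1 = cost[nb]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k1, k0 + 1)
                cost[node] = (c0, c1)
    return int(min(cost[root]))


def native_group_sizes(labeled: LabeledTree) -> list[int]:
    """Sizes of the maximal all-native subtrees (native leaf groups).

    A group is a maximal clan (one-cut component) whose leaves are all
    native; the groups partition the native leaf set.
    """
    tree = labeled.tree
    natives = labeled.native_set
    if not natives:
        return []
    if not labeled.intruder_set:
        return [len(natives)]
    g = tree.graph
    root = min(labeled.intruder_set)  # deterministic intruder root
    pure: dict = {}
    count: dict = {}
    order = []
    stack = [(root, None)]
    parent_of = {root: None}
    while stack:
        node, parent = stack.pop()
        order.append(node)
        for nb in g[node]:
            if nb != parent:
                parent_of[nb] = node
                stack.append((nb, node))
    for node in reversed(order):
        if isinstance(node, str):
            pure[node] = node in natives
            count[node] = 1 if node in natives else 0
        else:
            kids = [nb for nb in g[node] if nb != parent_of[node]]
            pure[node] = all(pure[k] for k in kids)
            count[node] = sum(count[k] for k in kids)
    sizes = []
    for node in order:
        parent = parent_of[node]
        if parent is None:
            continue  # root is an intruder leaf, never pure-native
        if pure[node] and count[node] > 0 and not pure[parent]:
            sizes.append(count[node])
    return sizes


def e_star(labeled: LabeledTree) -> float | None:
    """Equitability of the dispersal of natives across the tree.

    ``E* = [-sum (ci/N) ln(ci/N)] / ln(N)`` over the maximal native group
    sizes ``ci`` (``N`` natives total); 0 when the natives form a single
    group or ``N == 1``, and ``None`` (undefined) when there are no natives.
    """
    n = len(labeled.native_set)
    if n == 0:
        return None
    sizes = native_group_sizes(labeled)
    if n == 1 or len(sizes) == 1:
        return 0.0
    total = sum(sizes)
    h = -sum((c / total) * math.log(c / total) for c in sizes)
    return min(1.0, max(0.0, h / math.log(total)))


def _native_boundary(labeled: LabeledTree) -> int:
    """Edges leaving the minimal subtree spanning the natives.

    This is the minimum number of cuts isolating a single all-native
    component that contains every native: 1 for a perfect clan, 2 for a
    perfect slice.
    """
    tree = labeled.tree
    nodes = steiner_nodes(tree, list(labeled.native_set))
    return sum(
        1 for u, v in tree.graph.edges if (u in nodes) != (v in nodes)
    )


def classify_tree(labeled: LabeledTree) -> ClanReport:
    """Classify one labeled tree and compute both mixing indices."""
    n_native = len(labeled.native_set)
    n_intruder = len(labeled.intruder_set)
    if n_native == 0:
        return ClanReport(
            labeled.tree.tree_id, "absent", None, 0, 0, n_intruder, True
        )
    if n_intruder == 0:
        return ClanReport(
            labeled.tree.tree_id, "pure", 0.0, 0, n_native, 0, n_native <= 1
        )
    boundary = _native_boundary(labeled)
    if boundary == 1:
        cls = "perfect_clan"
    elif boundary == 2:
        cls = "perfect_slice"
    else:
        cls = "melange"
    return ClanReport(
        labeled.tree.tree_id,
        cls,
        e_star(labeled),
        p_score(labeled),
        n_native,
        n_intruder,
        n_native <= 1,
    )


# ---------------------------------------------------------------------------
# category rules


CategoryRule = Callable[[str, AnnotationTable], str | None]
"""Maps a leaf to ``"native"``, ``"intruder"`` or ``None`` (leaf excluded)."""


def taxon_rule(native_classes: Iterable[str]) -> CategoryRule:
    """Natives are leaves whose taxon class is in ``native_classes``.

    A class of ``"EC"`` matches every strain label EC1..EC30, so
    ``taxon_rule(["EC"])`` realises the E. coli vs non-E. coli partition and
    ``taxon_rule(["EC", "BAC"])``-style remappings support reanalyses that
    fold further taxa into the native side.
    """
    native_classes = tuple(native_classes)

    def rule(leaf: str, annotations: AnnotationTable) -> str | None:
        cls = annotations[leaf].taxon_class
        for nat in native_classes:
            if cls == nat or (nat == "EC" and cls.startswith("EC")):
                return "native"
        return "intruder"

    return rule


def pathogenicity_rule(leaf: str, annotations: AnnotationTable) -> str | None:
    """PATH leaves native, NON-PATH intruders, unknown (OTH) excluded."""
    p = annotations[leaf].pathogenicity
    if p == "PATH":
        return "native"
    if p == "NON-PATH":
        return "intruder"
    return None


def disease_rule(disease: str) -> CategoryRule:
    """Natives are PATH leaves annotated with the given disease."""

    def rule(leaf: str, annotations: AnnotationTable) -> str | None:
        rec = annotations[leaf]
        if rec.pathogenicity == "OTH":
            return None
        return "native" if rec.disease == disease else "intruder"

    return rule


def mge_rule(leaf: str, annotations: AnnotationTable) -> str | None:
    return "native" if annotations[leaf].taxon_class == "MGE" else "intruder"


NAMED_RULES: dict[str, CategoryRule] = {
    "ecoli": taxon_rule(["EC"]),
    "path": pathogenicity_rule,
    "mge": mge_rule,
}


def _resolve_rule(rule: str | CategoryRule) -> CategoryRule:
    if callable(rule):
        return rule
    try:
        return NAMED_RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown category rule {rule!r}; known: {sorted(NAMED_RULES)}"
        ) from None


def apply_rule(
    tree: GeneTree, annotations: AnnotationTable, rule: str | CategoryRule
) -> LabeledTree:
    """Resolve every leaf through the rule, restricting away excluded leaves."""
    rule = _resolve_rule(rule)
    unmapped = [leaf for leaf in tree.leaves if leaf not in annotations]
    if unmapped:
        raise ValidationError(
            f"{tree.tree_id}: leaves without annotation: {sorted(unmapped)}"
        )
    natives, intruders, excluded = [], [], []
    for leaf in tree.leaves:
        side = rule(leaf, annotations)
        if side == "native":
            natives.append(leaf)
        elif side == "intruder":
            intruders.append(leaf)
        else:
            excluded.append(leaf)
    if excluded:
        tree = restrict(tree, natives + intruders)
    return LabeledTree(tree, frozenset(natives), frozenset(intruders))


# ---------------------------------------------------------------------------
# forest level


@dataclass
class ForestSummary:
    counts: dict[str, int]  # per classification, incl. "absent"
    n_trees: int
    n_trivial: int
    mean_e_star_melange: float | None
    percentages: dict[str, float]
    reports: list[ClanReport]

    @property
    def presence_pct(self) -> float:
        """Share of trees where the native category is present at all."""
        present = self.n_trees - self.counts.get("absent", 0)
        return percentage([present], self.n_trees)


def percentage(counts: Sequence[int], total: int) -> float:
    """Share of ``total`` represented by ``sum(counts)``, in percent, 1 decimal."""
    if total <= 0:
        return 0.0
    return round(100.0 * sum(counts) / total, 1)


def forest_summary(
    forest: Iterable[GeneTree],
    annotations: AnnotationTable,
    category_rule: str | CategoryRule,
    support_cutoff: float | None = None,
    e_star_scope: str = "melange",
) -> ForestSummary:
    """Classify every tree of a forest and tabulate the class counts.

    ``support_cutoff`` collapses weakly supported internal edges before
    classification.  ``e_star_scope`` selects the trees over which the mean
    E* is taken (``"melange"`` or ``"non_pure"``).
    """
    if e_star_scope not in ("melange", "non_pure"):
        raise ValueError(f"unknown e_star_scope {e_star_scope!r}")
    reports: list[ClanReport] = []
    for tree in forest:
        if support_cutoff is not None:
            tree = collapse_low_support(tree, support_cutoff)
        reports.append(classify_tree(apply_rule(tree, annotations, category_rule)))

    counts = Counter(r.classification for r in reports)
    for cls in CLASSES + ("absent",):
        counts.setdefault(cls, 0)
    if e_star_scope == "melange":
        pool = [r.e_star for r in reports if r.classification == "melange"]
    else:
        pool = [
            r.e_star
            for r in reports
            if r.classification in ("perfect_clan", "perfect_slice", "melange")
        ]
    pool = [e for e in pool if e is not None]
    mean_e = sum(pool) / len(pool) if pool else None
    n_trees = len(reports)
    percentages = {
        cls: percentage([counts[cls]], n_trees) for cls in CLASSES + ("absent",)
    }
    return ForestSummary(
        counts=dict(counts),
        n_trees=n_trees,
        n_trivial=sum(1 for r in reports if r.trivial),
        mean_e_star_melange=mean_e,
        percentages=percentages,
        reports=reports,
    )


def find_mobile_modules(
    forest: Iterable[GeneTree],
    annotations: AnnotationTable,
    strains: Iterable[str] | None = None,
) -> list[list[str]]:
    """Candidate mobile modules of pathogenicity.

    Groups (size >= 2) of trees that (i) contain at least one mobile-element
    leaf, (ii) are pure under the pathogenicity rule (every cellular leaf
    with known lifestyle is pathogenic, p-score 0 with PATH natives), and
    (iii) share an identical strain presence/absence vector.  Groups are
    keyed by that vector and returned sorted.
    """
    strain_set = set(strains) if strains is not None else set(annotations.strains())
    groups: dict[frozenset, list[str]] = defaultdict(list)
    for tree in forest:
        leaves = tree.leaves
        recs = [annotations[leaf] for leaf in leaves]
        if not any(r.taxon_class == "MGE" for r in recs):
            continue
        lifestyles = {r.pathogenicity for r in recs if r.pathogenicity != "OTH"}
        if lifestyles != {"PATH"}:
            continue
        present = frozenset(
            r.genome_id for r in recs if r.genome_id in strain_set
        )
        groups[present].append(tree.tree_id)
    return sorted(
        (sorted(ids) for ids in groups.values() if len(ids) >= 2), key=lambda g: g[0]
    )


def write_reports(reports: Iterable[ClanReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tree_id\tclassification\te_star\tp_score\tn_native\tn_intruder\ttrivial\n"
        )
        for r in reports:
            e = "" if r.e_star is None else f"{r.e_star:.4f}"
            fh.write(
                f"{r.tree_id}\t{r.classification}\t{e}\t{r.p_score}"
                f"\t{r.n_native}\t{r.n_intruder}\t{int(r.trivial)}\n"
            )
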