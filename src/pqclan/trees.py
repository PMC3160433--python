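"""Unrooted gene trees and topology operations.

A gene tree is stored as an undirected :class:`networkx.Graph`: leaves are
string-named nodes (sequence identifiers), internal nodes are integers.
Internal edges may carry a bootstrap ``support`` attribute in [0, 100];
``None`` means "no support recorded".  Polytomies are permitted, degree-2
internal nodes are not (they are suppressed on construction).
"""

from __future__ import annotations

import itertools
from collections import deque
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx


class TreeError(ValueError):
    """Raised for malformed or invalid tree input."""


class GeneTree:
    """An unrooted, leaf-labelled tree with optional edge supports.

    Parameters
    ----------
    graph:
        Undirected tree whose string nodes are leaves and integer nodes are
        internal vertices.  Edges may carry a ``support`` attribute.
    tree_id:
        Identifier used in reports and exports.
    """

    __slots__ = ("graph", "tree_id")

    def __init__(self, graph: nx.Graph, tree_id: str = "tree"):
        self.graph = graph
        self.tree_id = tree_id

    # -- basic accessors ---------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if isinstance(n, str)]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.graph.nodes if isinstance(n, str))

    @property
    def internal_nodes(self) -> list[int]:
        return [n for n in self.graph.nodes if not isinstance(n, str)]

    def internal_edges(self) -> list[tuple]:
        return [
            (u, v)
            for u, v in self.graph.edges
            if not isinstance(u, str) and not isinstance(v, str)
        ]

    def support(self, u, v) -> float | None:
        return self.graph.edges[u, v].get("support")

    def copy(self) -> "GeneTree":
        return GeneTree(self.graph.copy(), self.tree_id)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTree({self.tree_id!r}, {self.n_leaves} leaves)"

    # -- topology ----------------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions induced by internal edges.

        Each split is a frozenset of the two leaf-side frozensets, a
        representation independent of rooting and node numbering.
        """
        all_leaves = frozenset(self.leaves)
        splits: set[frozenset] = set()
        for u, v in self.internal_edges():
            side = frozenset(self._leaves_on_side(u, v))
            splits.add(frozenset({side, all_leaves - side}))
        return splits

    def _leaves_on_side(self, keep, cut) -> list[str]:
        """Leaves reachable from ``keep`` when edge (keep, cut) is removed."""
        seen = {cut, keep}
        stack = [keep]
        out = []
        while stack:
            n = stack.pop()
            if isinstance(n, str):
                out.append(n)
            for nb in self.graph[n]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return out

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize as a Newick string, internal supports as node labels."""
        g = self.graph
        if g.number_of_nodes() == 1:
            (only,) = g.nodes
            return f"{only};"
        internals = self.internal_nodes
        if not internals:
            # two leaves joined by a single edge
            a, b = self.leaves
            return f"({a},{b});"
        root = internals[0]

        def fmt(node, parent) -> str:
            children = [nb for nb in g[node] if nb != parent]
            if not children:  # leaf
                return str(node)
            inner = ",".join(fmt(c, node) for c in children)
            label = ""
            if parent is not None:
                sup = g.edges[parent, node].get("support")
                if sup is not None:
                    label = format(sup, "g")
            return f"({inner}){label}"

        return fmt(root, None) + ";"


# ---------------------------------------------------------------------------
# construction


def _from_dendropy(dtree: dendropy.Tree, tree_id: str) -> GeneTree:
    g = nx.Graph()
    counter = itertools.count()
    node_id: dict = {}
    labels_seen: set[str] = set()

    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise TreeError(f"{tree_id}: unlabeled leaf")
            label = node.taxon.label
            if label in labels_seen:
                raise TreeError(f"{tree_id}: duplicate leaf name {label!r}")
            labels_seen.add(label)
            node_id[node] = label
        else:
            node_id[node] = next(counter)

    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        support = None
        if not node.is_leaf() and node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError as exc:
                raise TreeError(
                    f"{tree_id}: non-numeric internal label {node.label!r}"
                ) from exc
            if 0.0 < support < 1.0:
                # proportion convention (fractional values are unambiguous;
                # exactly 0 or 1 is kept as a percent)
                support *= 100.0
            if not 0.0 <= support <= 100.0:
                raise TreeError(f"{tree_id}: support {support} outside [0, 100]")
        g.add_edge(node_id[parent], node_id[node], support=support)

    if g.number_of_nodes() == 0:
        (only,) = (node_id[n] for n in dtree.preorder_node_iter())
        g.add_node(only)

    # unrooted interpretation: suppress a degree-2 root
    root = node_id[dtree.seed_node]
    _suppress_degree_two(g, root)
    return GeneTree(g, tree_id)


def _suppress_degree_two(g: nx.Graph, node) -> None:
    if isinstance(node, str) or node not in g or g.degree(node) != 2:
        return
    u, v = g[node]
    su = g.edges[node, u].get("support")
    sv = g.edges[node, v].get("support")
    if su is not None and sv is not None:
        support = max(su, sv)
    else:
        support = su if su is not None else sv
    g.remove_node(node)
    g.add_edge(u, v, support=support)


def parse_newick(text: str, tree_id: str = "tree") -> GeneTree:
    """Parse a single Newick record into a :class:`GeneTree`."""
    text = text.strip()
    if not text.endswith(";"):
        text += ";"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"{tree_id}: malformed Newick: {exc}") from exc
    return _from_dendropy(dtree, tree_id)


# ---------------------------------------------------------------------------
# operations


def collapse_low_support(tree: GeneTree, cutoff: float = 50.0) -> GeneTree:
    """Contract internal edges with support below ``cutoff``.

    Edges without a recorded support are kept.  The leaf set is unchanged;
    contraction produces polytomies.
    """
    if not 0.0 <= cutoff <= 100.0:
        raise ValueError(f"cutoff must be in [0, 100], got {cutoff}")
    g = tree.graph
    parent: dict = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in tree.internal_edges():
        sup = g.edges[u, v].get("support")
        if sup is not None and sup < cutoff:
            parent[find(u)] = find(v)

    new = nx.Graph()
    for n in g.nodes:
        new.add_node(find(n))
    for u, v, data in g.edges(data=True):
        ru, rv = find(u), find(v)
        if ru != rv:
            new.add_edge(ru, rv, **data)
    return GeneTree(new, tree.tree_id)


def restrict(tree: GeneTree, keep_leaves: Iterable[str]) -> GeneTree:
    """Restrict a tree to a leaf subset, suppressing degree-2 vertices.

    When two edges are merged the surviving support is the smaller of the
    recorded values (conservative), or the recorded one if only one exists.
    """
    keep = set(keep_leaves)
    missing = keep - set(tree.leaves)
    if missing:
        raise TreeError(f"{tree.tree_id}: leaves not in tree: {sorted(missing)}")
    if len(keep) < 2:
        g = nx.Graph()
        for leaf in keep:
            g.add_node(leaf)
        return GeneTree(g, tree.tree_id)

    g = tree.graph.copy()
    # iteratively prune non-kept pendant vertices
    queue = deque(n for n in g.nodes if g.degree(n) <= 1 and n not in keep)
    while queue:
        n = queue.popleft()
        if n not in g or n in keep:
            continue
        nbrs = list(g[n])
        g.remove_node(n)
        for nb in nbrs:
            if g.degree(nb) <= 1 and nb not in keep:
                queue.append(nb)
    # suppress degree-2 internal vertices
    for n in [x for x in g.nodes if not isinstance(x, str)]:
        if g.degree(n) == 2:
            u, v = g[n]
            su = g.edges[n, u].get("support")
            sv = g.edges[n, v].get("support")
            if su is not None and sv is not None:
                support = min(su, sv)
            else:
                support = su if su is not None else sv
            g.remove_node(n)
            g.add_edge(u, v, support=support)
    return GeneTree(g, tree.tree_id)


def relabel_leaves(tree: GeneTree, mapping: Mapping[str, str]) -> GeneTree:
    """Return a copy with leaves renamed through ``mapping``."""
    values = list(mapping.values())
    if len(values) != len(set(values)):
        raise TreeError("relabeling would create duplicate leaf names")
    return GeneTree(nx.relabel_nodes(tree.graph, dict(mapping)), tree.tree_id)


class PathTable:
    """Cached leaf-to-leaf paths of one tree.

    Used by the quartet machinery: provides the topological distance and the
    edge set of the path between any two leaves.
    """

    def __init__(self, tree: GeneTree):
        self._g = tree.graph
        self._cache: dict[tuple, tuple[int, frozenset]] = {}

    def path(self, a: str, b: str) -> tuple[int, frozenset]:
        key = (a, b) if a <= b else (b, a)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        # BFS from a to b
        prev = {a: None}
        queue = deque([a])
        while queue:
            n = queue.popleft()
            if n == b:
                break
            for nb in self._g[n]:
                if nb not in prev:
                    prev[nb] = n
                    queue.append(nb)
        if b not in prev:
            raise TreeError(f"no path between {a!r} and {b!r}")
        edges = []
        n = b
        while prev[n] is not None:
            p = prev[n]
            edges.append(frozenset((p, n)))
            n = p
        result = (len(edges), frozenset(edges))
        self._cache[key] = result
        return result

    def dist(self, a: str, b: str) -> int:
        return self.path(a, b)[0]

    def edges(self, a: str, b: str) -> frozenset:
        return self.path(a, b)[1]


def steiner_nodes(tree: GeneTree, terminals: Sequence[str]) -> set:
    """Vertices of the minimal subtree spanning ``terminals``."""
    term = set(terminals)
    g = tree.graph
    if not term:
        return set()
    degree = dict(g.degree)
    removed: set = set()
    queue = deque(n for n, d in degree.items() if d <= 1 and n not in term)
    while queue:
        n = queue.popleft()
        if n in removed or n in term:
            continue
        removed.add(n)
        for nb in g[n]:
            if nb in removed:
                continue
            degree[nb] -= 1
            if degree[nb] <= 1 and nb not in term:
                queue.append(nb)
    return set(g.nodes) - removed
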