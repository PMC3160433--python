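"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, own BFS/DFS)
and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque


# -- two-state parsimony ----------------------------------------------------


def brute_force_p_score(tree, natives) -> int:
    """Minimum bichromatic edge count over all internal-state assignments."""
    g = tree.graph
    natives = set(natives)
    internals = [n for n in g.nodes if not isinstance(n, str)]
    leaves = [n for n in g.nodes if isinstance(n, str)]
    if not internals:
        (a, b) = leaves if len(leaves) == 2 else (leaves[0], leaves[0])
        return int((a in natives) != (b in natives))
    best = None
    for bits in itertools.product((0, 1), repeat=len(internals)):
        state = {n: b for n, b in zip(internals, bits)}
        for leaf in leaves:
            state[leaf] = 0 if leaf in natives else 1
        changes = sum(1 for u, v in g.edges if state[u] != state[v])
        best = changes if best is None else min(best, changes)
    return best


# -- clan / slice enumeration ----------------------------------------------


def _components_without_edges(g, removed_edges):
    """Connected components after removing the given edges (own BFS)."""
    removed = {frozenset(e) for e in removed_edges}
    seen = set()
    comps = []
    for start in g.nodes:
        if start in seen:
            continue
        comp = {start}
        seen.add(start)
        queue = deque([start])
        while queue:
            n = queue.popleft()
            for nb in g[n]:
                if frozenset((n, nb)) in removed or nb in comp:
                    continue
                comp.add(nb)
                seen.add(nb)
                queue.append(nb)
        comps.append(comp)
    return comps


def enumerate_classification(tree, natives) -> str:
    """pure / perfect_clan / perfect_slice / melange by explicit cut tests."""
    g = tree.graph
    natives = set(natives)
    leaves = {n for n in g.nodes if isinstance(n, str)}
    intruders = leaves - natives
    if not intruders:
        return "pure"
    if not natives:
        return "absent"
    edges = list(g.edges)

    def leafset(comp):
        return {n for n in comp if isinstance(n, str)}

    for e in edges:
        for comp in _components_without_edges(g, [e]):
            if leafset(comp) == natives:
                return "perfect_clan"
    for e1, e2 in itertools.combinations(edges, 2):
        for comp in _components_without_edges(g, [e1, e2]):
            if leafset(comp) == natives:
                return "perfect_slice"
    return "melange"


def native_groups_by_enumeration(tree, natives) -> list[int]:
    """Sizes of maximal all-native one-cut components (clans)."""
    g = tree.graph
    natives = set(natives)
    leaves = {n for n in g.nodes if isinstance(n, str)}
    if not (leaves - natives):
        return [len(natives)]
    pure_clans = []
    for e in g.edges:
        for comp in _components_without_edges(g, [e]):
            ls = {n for n in comp if isinstance(n, str)}
            if ls and ls <= natives:
                pure_clans.append(frozenset(ls))
    maximal = [
        c for c in set(pure_clans)
        if not any(c < other for other in pure_clans)
    ]
    return sorted(len(c) for c in maximal)


# -- quartet topology -------------------------------------------------------


def quartet_split_by_paths(tree, a, b, c, d):
    """Split of {a,b,c,d} via node-disjointness of connecting paths."""
    g = tree.graph

    def path_nodes(x, y):
        prev = {x: None}
        queue = deque([x])
        while queue:
            n = queue.popleft()
            if n == y:
                break
            for nb in g[n]:
                if nb not in prev:
                    prev[nb] = n
                    queue.append(nb)
        out = set()
        n = y
        while n is not None:
            out.add(n)
            n = prev[n]
        return out

    for (p, q), (r, s) in (
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    ):
        if not (path_nodes(p, q) & path_nodes(r, s)):
            return frozenset({frozenset((p, q)), frozenset((r, s))})
    return None


def exhaustive_quartet_frequencies(tree, strain_of) -> dict:
    """Same-clan frequency per strain pair over all quartets (single copy)."""
    by_strain = {}
    for leaf in tree.leaves:
        s = strain_of.get(leaf)
        if s is not None:
            assert s not in by_strain, "oracle assumes single-copy trees"
            by_strain[s] = leaf
    strains = sorted(by_strain)
    same, cooc = {}, {}
    for quartet in itertools.combinations(strains, 4):
        leaves = [by_strain[s] for s in quartet]
        split = quartet_split_by_paths(tree, *leaves)
        if split is None:
            continue
        leaf_strain = {by_strain[s]: s for s in quartet}
        for s1, s2 in itertools.combinations(quartet, 2):
            cooc[frozenset((s1, s2))] = cooc.get(frozenset((s1, s2)), 0) + 1
        for cherry in split:
            x, y = tuple(cherry)
            key = frozenset((leaf_strain[x], leaf_strain[y]))
            same[key] = same.get(key, 0) + 1
    return {
        pair: same.get(pair, 0) / n for pair, n in cooc.items()
    }


# -- graph centralities -----------------------------------------------------


def brute_force_betweenness(g) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    scores = {n: 0.0 for n in nodes}

    def all_shortest_paths(s, t):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            n = queue.popleft()
            for nb in g[n]:
                if nb not in dist:
                    dist[nb] = dist[n] + 1
                    queue.append(nb)
        paths = []

        def extend(path):
            n = path[-1]
            if n == t:
                paths.append(path)
                return
            for nb in g[n]:
                if dist.get(nb) == dist[n] + 1 and dist[nb] <= dist.get(t, 0):
                    extend(path + [nb])

        if t in dist:
            extend([s])
        return paths

    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for n in nodes:
                if n in (s, t):
                    continue
                through = sum(1 for p in paths if n in p)
                scores[n] += through / len(paths)
    return scores


def brute_force_articulation_points(g) -> set:
    """Nodes whose removal disconnects the graph (own DFS connectivity)."""

    def connected(nodes, edges):
        nodes = list(nodes)
        if not nodes:
            return True
        seen = {nodes[0]}
        stack = [nodes[0]]
        adj = {n: set() for n in nodes}
        for u, v in edges:
            if u in adj and v in adj:
                adj[u].add(v)
                adj[v].add(u)
        while stack:
            n = stack.pop()
            for nb in adj[n]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(nodes)

    out = set()
    for node in g.nodes:
        rest = [n for n in g.nodes if n != node]
        if len(rest) >= 1 and not connected(rest, list(g.edges)):
            out.add(node)
    return out


# -- single linkage ---------------------------------------------------------


def union_find_families(all_seqs, linked_pairs) -> set[frozenset]:
    """Connected components by repeated set union."""
    groups = {s: {s} for s in all_seqs}
    for a, b in linked_pairs:
        ga, gb = groups[a], groups[b]
        if ga is gb:
            continue
        merged = ga | gb
        for s in merged:
            groups[s] = merged
    return {frozenset(gr) for gr in groups.values()}
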