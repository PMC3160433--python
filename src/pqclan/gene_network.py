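"""Sequence-level gene networks and per-component topology triage.

Nodes are sequences, edges homology hits passing identity/e-value filters;
each gene family falls into one connected component.  Per-component metrics
(density, clustering, diameter, betweenness, articulation points,
communities) support a fast classification of evolutionary mode: clique-like
components behave like conserved families, components broken into
communities bridged by high-betweenness nodes point at tinkering (fusion,
divergent expansion, mobile-element traffic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, pstdev
from typing import Iterable

import networkx as nx

from .families import pair_statistics
from .io import AnnotationTable, HomologyHit


@dataclass
class GeneNetworkComponent:
    component_id: str
    graph: nx.Graph  # node attr taxon_class; edge attrs identity, evalue


def _obligate_bridges(g: nx.Graph, articulation_points: set) -> set:
    """Articulation points whose removal leaves only components of size >= 2.

    Such nodes join non-trivial subgraphs (the barbell join pattern) rather
    than merely anchoring a pendant vertex.
    """
    out = set()
    for node in articulation_points:
        rest = g.subgraph(n for n in g.nodes if n != node)
        if all(len(c) >= 2 for c in nx.connected_components(rest)):
            out.add(node)
    return out


@dataclass
class ComponentMetrics:
    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    diameter: int
    betweenness: dict  # raw (unnormalized) shortest-path counts
    articulation_points: set
    communities: list[frozenset]
    local_articulation_points: set = field(default_factory=set)
    high_betweenness: set = field(default_factory=set)
    obligate_bridges: set = field(default_factory=set)
    degenerate: bool = False  # single-node component


def build_gene_network(
    hits: Iterable[HomologyHit],
    annotations: AnnotationTable | None = None,
    identity_min: float = 30.0,
    evalue_max: float = 1e-20,
) -> list[GeneNetworkComponent]:
    """Build the filtered sequence graph and materialize its components.

    Edges use best-direction hit statistics (identity >= ``identity_min``,
    e-value <= ``evalue_max``); an empty hit set yields an empty network.
    Components are ordered by their smallest member for determinism.
    """
    g = nx.Graph()
    hits = list(hits)
    for hit in hits:
        g.add_node(hit.query)
        g.add_node(hit.subject)
    for pair, st in pair_statistics(hits).items():
        if st.evalue <= evalue_max and st.identity_pct >= identity_min:
            a, b = sorted(pair)
            g.add_edge(a, b, identity=st.identity_pct, evalue=st.evalue)
    if annotations is not None:
        for node in g.nodes:
            if node in annotations:
                g.nodes[node]["taxon_class"] = annotations[node].taxon_class
    components = sorted(nx.connected_components(g), key=min)
    return [
        GeneNetworkComponent(f"C{i:05d}", g.subgraph(comp).copy())
        for i, comp in enumerate(components)
    ]


def detect_communities(graph: nx.Graph) -> list[frozenset]:
    """Modularity-maximizing partition by greedy agglomeration (deterministic)."""
    if graph.number_of_nodes() == 1:
        return [frozenset(graph.nodes)]
    comms = nx.community.greedy_modularity_communities(graph)
    return sorted((frozenset(c) for c in comms), key=min)


def component_metrics(
    component: GeneNetworkComponent | nx.Graph, betweenness_z: float = 2.0
) -> ComponentMetrics:
    """Topology metrics of one connected component.

    Betweenness is reported as raw shortest-path counts; nodes whose
    betweenness exceeds the component mean by ``betweenness_z`` standard
    deviations are flagged.  Local articulation points are articulation
    points of the community subgraphs.  A single-node component reports
    diameter 0 and clustering 1.0 by convention, flagged ``degenerate``.
    """
    g = component.graph if isinstance(component, GeneNetworkComponent) else component
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty component")
    if not nx.is_connected(g):
        raise ValueError("component metrics require a connected graph")
    if n == 1:
        (node,) = g.nodes
        return ComponentMetrics(
            1, 0, 1.0, 1.0, 0, {node: 0.0}, set(), [frozenset({node})],
            degenerate=True,
        )
    betweenness = nx.betweenness_centrality(g, normalized=False)
    communities = detect_communities(g)
    local_aps: set = set()
    for comm in communities:
        sub = g.subgraph(comm)
        if sub.number_of_nodes() >= 3:
            local_aps |= set(nx.articulation_points(sub))
    values = list(betweenness.values())
    mu, sigma = mean(values), pstdev(values)
    high = {
        node
        for node, b in betweenness.items()
        if sigma > 0 and b > mu + betweenness_z * sigma
    }
    aps = set(nx.articulation_points(g))
    return ComponentMetrics(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density=nx.density(g),
        avg_clustering=nx.average_clustering(g),
        diameter=nx.diameter(g),
        betweenness=betweenness,
        articulation_points=aps,
        communities=communities,
        local_articulation_points=local_aps,
        high_betweenness=high,
        obligate_bridges=_obligate_bridges(g, aps),
    )


def classify_topology(
    metrics: ComponentMetrics,
    clique_density: float = 0.8,
    bridged_density: float = 0.3,
) -> str:
    """Heuristic evolutionary-mode class from component topology.

    ``clique_like``: dense (density >= ``clique_density``) with no
    articulation points — conserved, clique-style families.  ``bridged``:
    sparse (density <= ``bridged_density``), or held together by an
    articulation point that either has significantly high betweenness or is
    an obligate bridge between non-trivial subgraphs (every side of its
    removal keeps >= 2 nodes).  Everything else is ``intermediate``.
    Thresholds are configuration defaults, not constants of the underlying
    biology.
    """
    if metrics.density >= clique_density and not metrics.articulation_points:
        return "clique_like"
    if metrics.density <= bridged_density:
        return "bridged"
    if metrics.articulation_points & metrics.high_betweenness:
        return "bridged"
    if metrics.obligate_bridges:
        return "bridged"
    return "intermediate"


def write_component_table(
    components: Iterable[GeneNetworkComponent], path
) -> None:
    """Per-component metric TSV for bulk triage of thousands of families."""
    with open(path, "w") as fh:
        fh.write(
            "component_id\tn_nodes\tn_edges\tdensity\tavg_clustering\tdiameter"
            "\tn_articulation_points\tn_communities\tclassification\n"
        )
        for comp in components:
            m = component_metrics(comp)
            fh.write(
                f"{comp.component_id}\t{m.n_nodes}\t{m.n_edges}\t{m.density:.4f}"
                f"\t{m.avg_clustering:.4f}\t{m.diameter}"
                f"\t{len(m.articulation_points)}\t{len(m.communities)}"
                f"\t{classify_topology(m)}\n"
            )


def export_component_graphml(component: GeneNetworkComponent, path) -> None:
    nx.write_graphml(component.graph, path)
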