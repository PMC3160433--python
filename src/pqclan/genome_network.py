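"""Identity-sliced genome networks.

Nodes are genomes; two genomes are joined when they share at least one gene
family whose best cross-genome member identity falls inside the requested
identity band.  Edge weights are the inverse of the shared-family count, the
display convention for shared-sequence networks.  The 100% band surfaces
candidate recent transfers between cellular genomes and mobile elements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .families import GeneFamily, pair_statistics
from .io import AnnotationTable, HomologyHit


@dataclass
class GenomeNetwork:
    graph: nx.Graph  # nodes: genome ids (attr taxon_class); edges: see build
    identity_band: tuple[float, float]

    @property
    def genomes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def shared_families(self) -> set[str]:
        out: set[str] = set()
        for _, _, data in self.graph.edges(data=True):
            out |= data["families"]
        return out

    def shared_sequences(self) -> set[str]:
        out: set[str] = set()
        for _, _, data in self.graph.edges(data=True):
            out |= data["sequences"]
        return out


def build_genome_network(
    families: Iterable[GeneFamily],
    hits: Iterable[HomologyHit],
    annotations: AnnotationTable,
    identity_band: tuple[float, float],
) -> GenomeNetwork:
    """Assemble the genome network for one identity band.

    A family is shared by genomes ``(g, h)`` within ``[lo, hi]`` iff the
    maximum identity over cross-genome member hit pairs lies in the band
    (band membership by maximum keeps "100% identical" families
    well-defined).  Edge attributes: ``families`` (ids), ``shared_count``,
    ``display_weight`` (= 1/shared_count), ``sequences`` (members attaining
    an in-band cross-genome identity on that edge).
    """
    lo, hi = identity_band
    if lo > hi:
        raise ValueError(f"identity band lower bound {lo} exceeds upper {hi}")
    identity = {
        pair: st.identity_pct for pair, st in pair_statistics(hits).items()
    }
    taxon_of = annotations.genomes()

    g = nx.Graph()
    for genome, taxon in taxon_of.items():
        g.add_node(genome, taxon_class=taxon)

    for fam in families:
        by_genome: dict[str, list[str]] = {}
        for seq in fam.members:
            by_genome.setdefault(annotations.genome_of(seq), []).append(seq)
        genomes = sorted(by_genome)
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1 :]:
                best = None
                pair_seqs: set[str] = set()
                for a in by_genome[ga]:
                    for b in by_genome[gb]:
                        ident = identity.get(frozenset((a, b)))
                        if ident is None:
                            continue
                        if best is None or ident > best:
                            best = ident
                if best is None or not (lo <= best <= hi):
                    continue
                for a in by_genome[ga]:
                    for b in by_genome[gb]:
                        ident = identity.get(frozenset((a, b)))
                        if ident is not None and lo <= ident <= hi:
                            pair_seqs |= {a, b}
                if g.has_edge(ga, gb):
                    data = g.edges[ga, gb]
                    data["families"].add(fam.family_id)
                    data["sequences"] |= pair_seqs
                else:
                    g.add_edge(
                        ga, gb, families={fam.family_id}, sequences=pair_seqs
                    )
    for _, _, data in g.edges(data=True):
        data["shared_count"] = len(data["families"])
        data["display_weight"] = 1.0 / data["shared_count"]
    return GenomeNetwork(g, (lo, hi))


def _modal_category(categories: Iterable[str]) -> str:
    """Most frequent COG category; ties broken by L first, then alphabetic."""
    counts = Counter(categories)
    if not counts:
        return "X"
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if "L" in tied:
        return "L"
    return tied[0]


def dominant_edge_function(
    network: GenomeNetwork, edge: tuple[str, str], annotations: AnnotationTable
) -> str:
    """Modal COG category of the sequences shared along one edge."""
    u, v = edge
    seqs = network.graph.edges[u, v]["sequences"]
    return _modal_category(annotations[s].cog for s in seqs)


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Each category's share of the column total, in percent, 1 decimal."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round(100.0 * n / total, 1) for c, n in counts.items()}


def summarize_categories(
    network: GenomeNetwork, annotations: AnnotationTable
) -> pd.DataFrame:
    """Per-COG-category counts of shared sequences and families in the band.

    Families are assigned a single category (the modal category of their
    shared sequences, L-first tie rule, X absorbing unknowns); percentage
    columns use the computed column totals.
    """
    seq_counts: Counter = Counter()
    for seq in network.shared_sequences():
        seq_counts[annotations[seq].cog] += 1

    fam_sequences: dict[str, set[str]] = {}
    for _, _, data in network.graph.edges(data=True):
        for fam in data["families"]:
            fam_sequences.setdefault(fam, set()).update(data["sequences"])
    fam_counts: Counter = Counter()
    for fam, seqs in fam_sequences.items():
        fam_counts[_modal_category(annotations[s].cog for s in seqs)] += 1

    categories = sorted(set(seq_counts) | set(fam_counts))
    seq_pct = category_percentages({c: seq_counts.get(c, 0) for c in categories})
    fam_pct = category_percentages({c: fam_counts.get(c, 0) for c in categories})
    return pd.DataFrame(
        {
            "n_sequences": [seq_counts.get(c, 0) for c in categories],
            "n_families": [fam_counts.get(c, 0) for c in categories],
            "pct_sequences": [seq_pct[c] for c in categories],
            "pct_families": [fam_pct[c] for c in categories],
        },
        index=pd.Index(categories, name="category"),
    )


def find_recent_transfer_candidates(
    network: GenomeNetwork, annotations: AnnotationTable
) -> list[tuple[str, str, str, str]]:
    """Per-family candidate records on cellular-genome <-> mobile-element edges.

    Intended for the [100, 100] band, where shared families are candidate
    recent exchanges.  Returns (cellular_genome, mobile_element, family_id,
    dominant category) sorted by genome pair then family.
    """
    taxon_of = network.graph.nodes
    out: list[tuple[str, str, str, str]] = []
    for u, v, data in network.graph.edges(data=True):
        tu = taxon_of[u]["taxon_class"]
        tv = taxon_of[v]["taxon_class"]
        if (tu == "MGE") == (tv == "MGE"):
            continue  # MGE-MGE or cellular-cellular
        cellular, mge = (u, v) if tv == "MGE" else (v, u)
        for fam in sorted(data["families"]):
            cat = _modal_category(annotations[s].cog for s in data["sequences"])
            out.append((cellular, mge, fam, cat))
    return sorted(out)


def export_graphml(
    network: GenomeNetwork, path, annotations: AnnotationTable | None = None
) -> None:
    """GraphML export with scalar edge attributes (sets joined with commas)."""
    g = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        g.add_node(node, **data)
    for u, v, data in network.graph.edges(data=True):
        attrs = {
            "shared_count": data["shared_count"],
            "display_weight": data["display_weight"],
            "families": ",".join(sorted(data["families"])),
        }
        if annotations is not None:
            attrs["dominant_category"] = dominant_edge_function(
                network, (u, v), annotations
            )
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, path)
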