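"""Gene-family clustering from homology hits.

Families are single-linkage clusters: connected components of the graph whose
edges are either plain hit pairs passing e-value/identity filters ("false
BBH") or reciprocal best hits passing the same filters ("true BBH").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .io import AnnotationTable, HomologyHit, ValidationError


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset
    mode: str = "false_bbh"
    identity_min: float = 0.0
    evalue_max: float = float("inf")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PairStats:
    """Best-direction statistics for an unordered sequence pair.

    When the two BLAST directions disagree, the pair passes a filter if the
    better direction passes (single linkage is permissive by design).
    """

    identity_pct: float
    evalue: float
    bitscore: float


def pair_statistics(hits: Iterable[HomologyHit]) -> dict[frozenset, PairStats]:
    """Collapse a hit stream to best-direction statistics per unordered pair."""
    stats: dict[frozenset, PairStats] = {}
    for hit in hits:
        if hit.is_self:
            continue
        old = stats.get(hit.pair)
        if old is None:
            stats[hit.pair] = PairStats(hit.identity_pct, hit.evalue, hit.bitscore)
        else:
            stats[hit.pair] = PairStats(
                max(old.identity_pct, hit.identity_pct),
                min(old.evalue, hit.evalue),
                max(old.bitscore, hit.bitscore),
            )
    return stats


def reciprocal_best_hits(
    hits: Iterable[HomologyHit], genome_of: Mapping[str, str] | AnnotationTable
) -> set[frozenset]:
    """Unordered pairs (a, b) that are mutual best hits between their genomes.

    ``b`` must be ``a``'s best-scoring subject within ``b``'s genome and vice
    versa.  Ties on bit score are broken by lower e-value, then lexicographic
    subject id, which yields a unique stable winner.  Self-hits are ignored.
    """
    if isinstance(genome_of, AnnotationTable):
        table = genome_of
        genome_of = {s: table.genome_of(s) for s in table}

    # best[(query, target_genome)] = (subject, sort_key)
    best: dict[tuple[str, str], tuple[str, tuple]] = {}
    for hit in hits:
        if hit.is_self:
            continue
        for seq in (hit.query, hit.subject):
            if seq not in genome_of:
                raise ValidationError(f"sequence {seq!r} has no genome mapping")
        target_genome = genome_of[hit.subject]
        key = (-hit.bitscore, hit.evalue, hit.subject)
        slot = (hit.query, target_genome)
        if slot not in best or key < best[slot][1]:
            best[slot] = (hit.subject, key)

    pairs: set[frozenset] = set()
    for (query, _), (subject, _) in best.items():
        back = best.get((subject, genome_of[query]))
        if back is not None and back[0] == query:
            pairs.add(frozenset((query, subject)))
    return pairs


def cluster_families(
    hits: Iterable[HomologyHit],
    mode: str = "false_bbh",
    identity_min: float = 70.0,
    evalue_max: float = 1e-20,
    annotations: AnnotationTable | None = None,
    universe: Iterable[str] = (),
) -> list[GeneFamily]:
    """Single-linkage gene families from a hit table.

    Parameters
    ----------
    mode:
        ``"false_bbh"`` links any hit pair passing the filters;
        ``"true_bbh"`` links only reciprocal-best pairs passing the same
        filters (requires ``annotations`` for the genome mapping).
    identity_min, evalue_max:
        Edge filters; a pair passes if its best direction passes.
    universe:
        Extra sequence ids emitted as singleton families even if hitless;
        sequences present in ``annotations`` are always included, which keeps
        the family partition total over the sequence universe.
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    if mode not in ("false_bbh", "true_bbh"):
        raise ValueError(f"unknown mode {mode!r}")

    hits = list(hits)
    stats = pair_statistics(hits)
    passing = {
        pair
        for pair, st in stats.items()
        if st.evalue <= evalue_max and st.identity_pct >= identity_min
    }
    if mode == "true_bbh":
        if annotations is None:
            raise ValueError("true_bbh mode requires an annotation table")
        passing &= reciprocal_best_hits(hits, annotations)

    g = nx.Graph()
    for hit in hits:
        g.add_node(hit.query)
        g.add_node(hit.subject)
    g.add_nodes_from(universe)
    if annotations is not None:
        g.add_nodes_from(annotations)
    for pair in passing:
        a, b = sorted(pair)
        g.add_edge(a, b)

    components = sorted(nx.connected_components(g), key=min)
    return [
        GeneFamily(f"F{i:05d}", frozenset(comp), mode, identity_min, evalue_max)
        for i, comp in enumerate(components)
    ]


def write_family_tables(
    families: Iterable[GeneFamily],
    membership_path,
    summary_path,
    annotations: AnnotationTable | None = None,
) -> None:
    """Export family membership and a per-family size/composition summary."""
    families = list(families)
    with open(membership_path, "w") as fh:
        fh.write("family_id\tsequence_id\n")
        for fam in families:
            for seq in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{seq}\n")
    with open(summary_path, "w") as fh:
        fh.write("family_id\tn_members\ttaxon_class_counts\n")
        for fam in families:
            if annotations is None:
                comp = ""
            else:
                counts: dict[str, int] = {}
                for seq in fam.members:
                    cls = annotations[seq].taxon_class if seq in annotations else "?"
                    counts[cls] = counts.get(cls, 0) + 1
                comp = ",".join(f"{k}:{v}" for k, v in sorted(counts.items()))
            fh.write(f"{fam.family_id}\t{len(fam)}\t{comp}\n")
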