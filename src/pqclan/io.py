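"""Readers and writers for the toolkit's external formats.

Covers Newick forests, 12-column tabular homology hits (BLAST ``outfmt 6``
layout), TSV annotation tables, Nexus distance matrices (TAXA + DISTANCES
blocks, for split-network software), and graph exports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .trees import GeneTree, TreeError, parse_newick


class FormatError(ValueError):
    """Raised when a tabular file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# forests


def _split_newick_records(text: str) -> list[str]:
    records = [rec.strip() for rec in text.split(";")]
    return [rec for rec in records if rec]


def read_forest(paths: Iterable[str | Path] | str | Path) -> list[GeneTree]:
    """Read one or more Newick files into a list of :class:`GeneTree`.

    Each file may hold several Newick records.  Tree ids are derived from the
    file stem, suffixed with the record index when a file holds more than one
    record.  The root of each record is treated as an unlabeled internal node
    (unrooted interpretation); internal-node labels are bootstrap supports.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        paths = sorted(path.glob("*.nwk")) if path.is_dir() else [path]
    forest: list[GeneTree] = []
    for path in paths:
        path = Path(path)
        records = _split_newick_records(path.read_text())
        for i, record in enumerate(records):
            tree_id = path.stem if len(records) == 1 else f"{path.stem}:{i}"
            try:
                forest.append(parse_newick(record + ";", tree_id))
            except TreeError as exc:
                raise TreeError(f"{path} record {i}: {exc}") from exc
    return forest


def write_forest(forest: Iterable[GeneTree], path: str | Path) -> None:
    """Write a forest as one Newick record per line."""
    with open(path, "w") as fh:
        for tree in forest:
            fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# homology hits


@dataclass(frozen=True)
class HomologyHit:
    """One record of an all-vs-all similarity search (outfmt-6 layout)."""

    query: str
    subject: str
    identity_pct: float
    aln_length: int
    evalue: float
    bitscore: float

    @property
    def is_self(self) -> bool:
        return self.query == self.subject

    @property
    def pair(self) -> frozenset:
        return frozenset((self.query, self.subject))


def read_hits(path: str | Path) -> Iterator[HomologyHit]:
    """Stream 12-column tab-separated hits.

    Columns follow the standard tabular layout: query, subject, %identity,
    alignment length, mismatches, gap opens, qstart, qend, sstart, send,
    e-value, bit score.  Wrong column counts raise :class:`FormatError`
    naming the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, found {len(fields)}"
                )
            try:
                hit = HomologyHit(
                    query=fields[0],
                    subject=fields[1],
                    identity_pct=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= hit.identity_pct <= 100.0:
                raise ValidationError(
                    f"{path}:{lineno}: identity {hit.identity_pct} outside [0, 100]"
                )
            if hit.evalue < 0:
                raise ValidationError(f"{path}:{lineno}: negative e-value")
            yield hit


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back to the 12-column tabular layout (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity_pct:.2f}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# annotations

TAXON_CLASSES = frozenset({"MGE", "EUK", "ARC", "BAC"} | {f"EC{i}" for i in range(1, 31)})
PATHOGENICITY = frozenset({"PATH", "NON-PATH", "OTH"})
DISEASES = frozenset({"URI", "HEM", "GAS", "OTH", "none"})
COG_CATEGORIES = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

_ANNOTATION_FIELDS = (
    "sequence_id",
    "genome_id",
    "taxon_class",
    "pathogenicity",
    "disease",
    "cog",
)


@dataclass(frozen=True)
class AnnotationRecord:
    genome_id: str
    taxon_class: str
    pathogenicity: str
    disease: str
    cog: str


class AnnotationTable:
    """Per-sequence annotation: genome, taxon class, pathogenicity, disease, COG.

    Invariants are enforced on construction: category tokens must come from
    the controlled vocabularies, a disease other than ``none`` requires a
    pathogenic host, and every sequence maps to exactly one record.
    """

    def __init__(self, records: Mapping[str, AnnotationRecord]):
        for seq_id, rec in records.items():
            self._validate(seq_id, rec)
        self._records = dict(records)

    @staticmethod
    def _validate(seq_id: str, rec: AnnotationRecord) -> None:
        if rec.taxon_class not in TAXON_CLASSES:
            raise ValidationError(f"{seq_id}: unknown taxon class {rec.taxon_class!r}")
        if rec.pathogenicity not in PATHOGENICITY:
            raise ValidationError(
                f"{seq_id}: unknown pathogenicity {rec.pathogenicity!r}"
            )
        if rec.disease not in DISEASES:
            raise ValidationError(f"{seq_id}: unknown disease {rec.disease!r}")
        if rec.disease != "none" and rec.pathogenicity != "PATH":
            raise ValidationError(
                f"{seq_id}: disease {rec.disease!r} requires pathogenicity PATH"
            )
        if rec.cog not in COG_CATEGORIES:
            raise ValidationError(f"{seq_id}: unknown COG category {rec.cog!r}")

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __getitem__(self, seq_id: str) -> AnnotationRecord:
        try:
            return self._records[seq_id]
        except KeyError:
            raise KeyError(f"sequence {seq_id!r} has no annotation") from None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def items(self):
        return self._records.items()

    def genome_of(self, seq_id: str) -> str:
        return self[seq_id].genome_id

    def genomes(self) -> dict[str, str]:
        """Map genome id -> taxon class."""
        return {rec.genome_id: rec.taxon_class for rec in self._records.values()}

    def strains(self) -> list[str]:
        """Genome ids whose taxon class is a strain label (EC1..EC30), sorted."""
        out = {
            rec.genome_id
            for rec in self._records.values()
            if rec.taxon_class.startswith("EC")
        }
        return sorted(out)

    def genome_pathogenicity(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rec in self._records.values():
            out.setdefault(rec.genome_id, rec.pathogenicity)
        return out


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV annotation table with a header naming the six columns."""
    records: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ANNOTATION_FIELDS:
            raise FormatError(
                f"{path}: header must be {list(_ANNOTATION_FIELDS)}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_ANNOTATION_FIELDS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_ANNOTATION_FIELDS)} columns"
                )
            seq_id = fields[0]
            if seq_id in records:
                raise ValidationError(f"{path}:{lineno}: duplicate sequence {seq_id!r}")
            records[seq_id] = AnnotationRecord(*fields[1:])
    return AnnotationTable(records)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_FIELDS) + "\n")
        for seq_id, rec in sorted(table.items()):
            fh.write(
                f"{seq_id}\t{rec.genome_id}\t{rec.taxon_class}"
                f"\t{rec.pathogenicity}\t{rec.disease}\t{rec.cog}\n"
            )


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with optional missing pairs."""

    taxa: tuple[str, ...]
    values: np.ndarray
    missing_mask: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} taxa"
            )
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def write_nexus_distances(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a Nexus file with TAXA and DISTANCES blocks.

    The output is consumable by standard split-network software; a round trip
    through :func:`read_nexus_distances` preserves values to 6 decimals.
    """
    if matrix.missing_mask:
        raise ValidationError(
            "distance matrix has missing pairs; impute before writing Nexus"
        )
    taxa = matrix.taxa
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={len(taxa)};"]
    lines.append("    TAXLABELS " + " ".join(taxa) + ";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN DISTANCES;")
    lines.append(f"    DIMENSIONS NTAX={len(taxa)};")
    lines.append("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;")
    lines.append("    MATRIX")
    for i, taxon in enumerate(taxa):
        row = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(len(taxa)))
        lines.append(f"        {taxon} {row}")
    lines.append("    ;")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nexus_distances(path: str | Path) -> DistanceMatrix:
    """Parse a Nexus DISTANCES block written by :func:`write_nexus_distances`."""
    text = Path(path).read_text()
    match = re.search(r"BEGIN DISTANCES;(.*?)END;", text, re.S | re.I)
    if match is None:
        raise FormatError(f"{path}: no DISTANCES block")
    block = match.group(1)
    mat = re.search(r"MATRIX(.*?);", block, re.S | re.I)
    if mat is None:
        raise FormatError(f"{path}: no MATRIX statement")
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in mat.group(1).strip().splitlines():
        fields = line.split()
        if not fields:
            continue
        taxa.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    return DistanceMatrix(tuple(taxa), np.array(rows))
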