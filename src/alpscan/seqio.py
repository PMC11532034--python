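"""Shared record types and on-disk formats.

Everything downstream consumes :class:`ProteinRecord`, :class:`DomainAnnotation`
and :class:`Alignment`. Coordinates are 1-based inclusive throughout the
package, matching how residue positions are reported in the literature;
0-based half-open conversions are internal to individual functions.

File formats handled here: plain and aligned FASTA ('-' gaps), Clustal ``.aln``
(sequences only, the conservation line is ignored), a tab-separated domain
annotation table, and Newick trees.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues a ProteinRecord may contain ('X' = unknown residue)
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"


class SeqioError(ValueError):
    """Malformed input artifact (FASTA, domain table, alignment, tree)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: unique whitespace-free id plus uppercase sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqioError(f"protein id must be non-empty without whitespace: {self.id!r}")
        if len(self.sequence) < 1:
            raise SeqioError(f"empty sequence for protein {self.id!r}")
        if self.sequence != self.sequence.upper():
            raise SeqioError(f"sequence for {self.id!r} must be uppercase")
        bad = sorted(set(self.sequence) - VALID_RESIDUES)
        if bad:
            raise SeqioError(
                f"non-amino-acid characters in {self.id!r}: {', '.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class DomainType(enum.Enum):
    """Domain vocabulary of the ALP repertoire.

    MAD = membrane-anchoring domain, ABD = archaeal big domain, RBH =
    right-handed beta-helical domain, TG = transglutaminase-like domain,
    PMB = pseudomurein-binding repeat, OTHER = anything else.
    """

    MAD = "MAD"
    ABD = "ABD"
    RBH = "RBH"
    TG = "TG"
    PMB = "PMB"
    OTHER = "OTHER"


class AnnotationSource(enum.Enum):
    EXTERNAL = "external"
    DETECTED = "detected"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class DomainAnnotation:
    """A typed 1-based inclusive interval on one protein."""

    protein_id: str
    domain_type: DomainType
    start: int
    end: int
    source: AnnotationSource

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SeqioError(
                f"invalid interval {self.start}..{self.end} on {self.protein_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Alignment:
    """Multiple sequence alignment: ordered (id, gapped sequence) rows."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqioError("alignment has no rows")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise SeqioError("alignment rows have unequal lengths")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise SeqioError("duplicate ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, i: int) -> str:
        return self.records[i][1]

    def ungapped(self, i: int) -> str:
        return self.records[i][1].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; sequences are uppercased, trailing '*' stripped.

    Raises :class:`SeqioError` on duplicate ids, empty files or residues
    outside the 20 standard amino acids plus 'X'.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqioError(f"duplicate id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise SeqioError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal ``.aln`` file.

    Format is inferred from the first line when ``fmt`` is None: Clustal
    files start with a ``CLUSTAL`` header.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    return Alignment(records=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (one row per line)."""
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["protein_id", "domain_type", "start", "end", "source"]


def read_domain_table(
    path: str | Path,
    proteins: Sequence[ProteinRecord] | None = None,
) -> list[DomainAnnotation]:
    """Read the tab-separated domain annotation table.

    Dialect: mandatory header ``protein_id  domain_type  start  end  source``,
    '#' comment lines ignored. Rows are validated and returned sorted by
    (protein_id, start). When ``proteins`` is given, every annotation must
    reference a known protein id and lie within its sequence bounds.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SeqioError(f"domain table missing columns: {missing}")
    annotations: list[DomainAnnotation] = []
    for row in df.itertuples(index=False):
        try:
            dtype = DomainType(row.domain_type)
        except ValueError:
            raise SeqioError(f"unknown domain_type {row.domain_type!r}") from None
        try:
            source = AnnotationSource(row.source)
        except ValueError:
            raise SeqioError(f"unknown source {row.source!r}") from None
        ann = DomainAnnotation(
            protein_id=str(row.protein_id),
            domain_type=dtype,
            start=int(row.start),
            end=int(row.end),
            source=source,
        )
        annotations.append(ann)
    if proteins is not None:
        by_id = {p.id: p for p in proteins}
        for ann in annotations:
            if ann.protein_id not in by_id:
                raise SeqioError(f"annotation references unknown protein {ann.protein_id!r}")
            if ann.end > len(by_id[ann.protein_id]):
                raise SeqioError(
                    f"annotation {ann.start}..{ann.end} exceeds length of {ann.protein_id!r}"
                )
    annotations.sort(key=lambda a: (a.protein_id, a.start, a.end))
    return annotations


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    rows = [
        (a.protein_id, a.domain_type.value, a.start, a.end, a.source.value)
        for a in sorted(annotations, key=lambda a: (a.protein_id, a.start, a.end))
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def group_by_protein(annotations: Iterable[DomainAnnotation]) -> dict[str, list[DomainAnnotation]]:
    """Bucket annotations per protein, each bucket sorted by start."""
    out: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        out.setdefault(a.protein_id, []).append(a)
    for anns in out.values():
        anns.sort(key=lambda a: (a.start, a.end))
    return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a :class:`alpscan.phylo.PhyloTree` to a Newick file.

    Branch lengths are written for every edge; bootstrap supports, where
    present, appear as integer internal-node labels. A tree with fewer than
    two leaves is an error.
    """
    newick = tree.to_newick()
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file back into a :class:`alpscan.phylo.PhyloTree`."""
    from .phylo import PhyloTree

    return PhyloTree.from_newick(Path(path).read_text())
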