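"""Readers/writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; human-readable
reports use 1-based inclusive positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

# Twenty standard residues, no ambiguity codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class DuplicateIdError(ValueError):
    """Raised when two records in one collection share an identifier."""


@dataclass(frozen=True)
class SeqRecord:
    """One molecule (protein or nucleotide) with its labels.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Residue text; stored uppercase.
    species : str
        Free-text species label, may be empty.
    gene : str
        Gene label such as ``"PMEL"`` or ``"gpnmb-like"``.
    moltype : str
        ``"protein"`` or ``"dna"``; inferred from the alphabet when not given.
    """

    id: str
    seq: str
    species: str = ""
    gene: str = ""
    moltype: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        moltype = self.moltype or infer_moltype(seq)
        if moltype not in ("protein", "dna"):
            raise ValueError(f"record {self.id!r}: unknown moltype {moltype!r}")
        alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside the "
                f"{moltype} alphabet"
            )
        object.__setattr__(self, "moltype", moltype)

    def __len__(self) -> int:
        return len(self.seq)


def infer_moltype(seq: str) -> str:
    """Infer ``"dna"`` when every residue is A/C/G/T/N, else ``"protein"``."""
    return "dna" if set(seq.upper()) <= DNA_ALPHABET else "protein"


@dataclass(frozen=True)
class GeneTableRow:
    """One gene on a chromosome, ranked by ordinal position."""

    chrom: str
    ordinal: int
    symbol: str
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ValueError("ordinal must be >= 0")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")
        object.__setattr__(self, "symbol", self.symbol.upper())


@dataclass(frozen=True)
class ExonTable:
    """Ordered exon lengths (bp) for one gene, plus the CDS start offset."""

    gene: str
    species: str
    exon_lengths: tuple[int, ...]
    cds_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_lengths", tuple(int(x) for x in self.exon_lengths))
        if not self.exon_lengths:
            raise ValueError(f"{self.gene}: no exons")
        if any(x <= 0 for x in self.exon_lengths):
            raise ValueError(f"{self.gene}: exon lengths must be > 0")
        if self.cds_offset < 0 or self.cds_offset >= sum(self.exon_lengths):
            raise ValueError(f"{self.gene}: cds_offset out of transcript")

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, moltype: str | None = None) -> list[SeqRecord]:
    """Read a multi-FASTA file into :class:`SeqRecord` objects.

    The first header token is the id; a second token, when present, is kept
    as the gene label; ``species=``/``gene=`` key-value tokens override.
    Sequences are uppercased and the moltype inferred from the alphabet
    unless ``moltype`` is forced.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        gene = ""
        species = ""
        tokens = rec.description.split()[1:]
        for tok in tokens:
            if tok.startswith("species="):
                species = tok[len("species="):]
            elif tok.startswith("gene="):
                gene = tok[len("gene="):]
        if not gene and tokens and "=" not in tokens[0]:
            gene = tokens[0]
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq), species=species, gene=gene,
                      moltype=moltype or "")
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA, embedding gene/species labels."""
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate ids in output collection")
    with open(path, "w") as fh:
        for r in records:
            desc = []
            if r.gene:
                desc.append(f"gene={r.gene}")
            if r.species:
                desc.append(f"species={r.species}")
            header = " ".join([r.id, *desc])
            fh.write(f">{header}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


def to_biopython(record: SeqRecord) -> _BioSeqRecord:
    """Convert to a Biopython record (used by alignment backends)."""
    return _BioSeqRecord(Seq(record.seq), id=record.id, description="")


# ---------------------------------------------------------------------------
# Gene tables (TSV: chrom, ordinal, symbol, strand)
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ("chrom", "ordinal", "symbol", "strand")


def read_gene_table(path) -> list[GeneTableRow]:
    """Read a TSV gene-order table, sort by (chrom, ordinal) and validate.

    Ordinals are rank positions along a chromosome: gaps are allowed (they
    arise after filtering) but duplicates within one chromosome are not.
    """
    rows: list[GeneTableRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header) != GENE_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {GENE_TABLE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, ordinal, symbol, strand = parts
            rows.append(GeneTableRow(chrom=chrom, ordinal=int(ordinal),
                                     symbol=symbol, strand=strand))
    rows.sort(key=lambda r: (r.chrom, r.ordinal))
    for a, b in zip(rows, rows[1:]):
        if a.chrom == b.chrom and a.ordinal == b.ordinal:
            raise ValueError(
                f"{path}: non-monotone ordinals on {a.chrom}: "
                f"{a.symbol}/{b.symbol} both at {a.ordinal}"
            )
    return rows


def write_gene_table(rows: Sequence[GeneTableRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in sorted(rows, key=lambda r: (r.chrom, r.ordinal)):
            fh.write(f"{r.chrom}\t{r.ordinal}\t{r.symbol}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Exon tables (TSV: gene, species, comma-separated lengths, cds_offset)
# ---------------------------------------------------------------------------

EXON_TABLE_COLUMNS = ("gene", "species", "exon_lengths", "cds_offset")


def read_exon_tables(path) -> list[ExonTable]:
    tables: list[ExonTable] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header) != EXON_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {EXON_TABLE_COLUMNS}, got {header}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, species, lengths, cds_offset = line.split("\t")
            tables.append(ExonTable(
                gene=gene, species=species,
                exon_lengths=tuple(int(x) for x in lengths.split(",")),
                cds_offset=int(cds_offset),
            ))
    return tables


def write_exon_tables(tables: Iterable[ExonTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXON_TABLE_COLUMNS) + "\n")
        for t in tables:
            lengths = ",".join(str(x) for x in t.exon_lengths)
            fh.write(f"{t.gene}\t{t.species}\t{lengths}\t{t.cds_offset}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path) -> None:
    """Write a :class:`pkat.phylo.PhyloTree` as Newick with branch lengths
    and integer support values as internal node labels."""
    from pkat.phylo import PhyloTree

    if not isinstance(tree, PhyloTree):
        raise TypeError("write_newick expects a PhyloTree")
    if len(tree.leaf_names()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if any(not name for name in tree.leaf_names()):
        raise ValueError("unnamed leaf")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path):
    """Parse a Newick file back into a :class:`pkat.phylo.PhyloTree`."""
    from pkat.phylo import PhyloTree

    with open(path) as fh:
        text = fh.read().strip()
    return PhyloTree.from_newick(text)
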