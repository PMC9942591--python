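"""Alignment and sequence I/O.

Reads multiple sequence alignments (FASTA or Clustal), validates them,
detects the alphabet, and maintains the query-position coordinate system:
conservation results are ultimately reported per ungapped query position,
so we keep an explicit map from query positions to MSA columns.

Normalisation on read: sequences are upper-cased, '.' gaps become '-',
'U' becomes 'T' in nucleotide mode, and ambiguity codes collapse to the
missing-data symbol ('X' for protein, 'N' for nucleotide).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import AlignIO, SeqIO

from .errors import (
    EmptyAlignmentError,
    ParseError,
    QueryMissingError,
    UnequalLengthError,
)

Alphabet = Literal["protein", "nucleotide"]

GAP = "-"
MISSING = {"protein": "X", "nucleotide": "N"}

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_LETTERS = set("ACGT")

# IUPAC nucleotide ambiguity codes (everything that is not ACGTU/N/gap)
_NT_AMBIGUOUS = set("RYSWKMBDHV")
# Protein ambiguity codes collapsed to X
_AA_AMBIGUOUS = set("BZJUO")

#: fraction of ACGTU characters above which an alignment is called nucleotide
NUCLEOTIDE_FRACTION = 0.85


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; residues may include '-' gaps and X/N missing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """A query-anchored multiple sequence alignment."""

    records: list[SequenceRecord]
    query_id: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise UnequalLengthError(
                f"alignment records differ in length: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.query_id not in set(ids):
            raise QueryMissingError(
                f"query {self.query_id!r} is not among the alignment records"
            )

    @property
    def n_sites(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def query(self) -> SequenceRecord:
        for r in self.records:
            if r.id == self.query_id:
                return r
        raise QueryMissingError(self.query_id)

    def column(self, i: int) -> dict[str, str]:
        """Mapping taxon id -> character at MSA column ``i``."""
        return {r.id: r.residues[i] for r in self.records}

    def subset(self, keep_ids: Iterable[str], drop_all_gap: bool = True) -> "Alignment":
        """Restrict to the given taxa, optionally dropping all-gap columns."""
        keep = set(keep_ids)
        records = [r for r in self.records if r.id in keep]
        if drop_all_gap and records:
            missing = MISSING[self.alphabet]
            cols = [
                i
                for i in range(len(records[0].residues))
                if any(r.residues[i] not in (GAP, missing) for r in records)
            ]
            records = [
                SequenceRecord(r.id, "".join(r.residues[i] for i in cols))
                for r in records
            ]
        return Alignment(records=records, query_id=self.query_id, alphabet=self.alphabet)


@dataclass(frozen=True)
class QueryPositionMap:
    """Map from 1-based ungapped query position to 0-based MSA column."""

    msa_col_for_query_pos: tuple[int, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.msa_col_for_query_pos)

    def column(self, query_pos: int) -> int:
        """MSA column (0-based) of the given 1-based query position."""
        return self.msa_col_for_query_pos[query_pos - 1]


def _normalize(seq: str, alphabet: Alphabet) -> str:
    s = seq.upper().replace(".", GAP)
    if alphabet == "nucleotide":
        s = s.replace("U", "T")
        out = []
        for c in s:
            if c in NUCLEOTIDE_LETTERS or c == GAP:
                out.append(c)
            else:
                out.append("N")
        return "".join(out)
    out = []
    for c in s:
        if c in PROTEIN_LETTERS or c == GAP:
            out.append(c)
        else:
            out.append("X")
    return "".join(out)


def detect_alphabet(records: Sequence[SequenceRecord]) -> Alphabet:
    """Call an alignment nucleotide when >= 85% of its informative characters
    are in {A, C, G, T, U}; otherwise protein.

    Gaps, 'X' and 'N' are ignored. Case-insensitive and order-independent.
    """
    total = 0
    nt = 0
    for rec in records:
        for c in rec.residues.upper():
            if c in (GAP, ".", "X", "N"):
                continue
            total += 1
            if c in "ACGTU":
                nt += 1
    if total == 0:
        raise EmptyAlignmentError("no informative characters in any record")
    return "nucleotide" if nt / total >= NUCLEOTIDE_FRACTION else "protein"


def _parse_records(path: str | Path, format: str) -> list[SequenceRecord]:
    fmt = {"fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ParseError(f"unsupported alignment format {format!r}")
    try:
        if fmt == "fasta":
            seqs = list(SeqIO.parse(str(path), "fasta"))
        else:
            aln = AlignIO.read(str(path), "clustal")
            seqs = list(aln)
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
    if not seqs:
        raise ParseError(f"no sequences found in {path}")
    return [SequenceRecord(s.id, str(s.seq)) for s in seqs]


def read_alignment(
    path: str | Path,
    format: Literal["fasta", "clustal"],
    query_id: str,
    alphabet: Alphabet | None = None,
) -> Alignment:
    """Read and validate a query-anchored MSA.

    Parameters
    ----------
    path, format
        Alignment file and its format ('fasta' or 'clustal').
    query_id
        Id of the query record; must be present in the file.
    alphabet
        Optional override of the automatic alphabet detection.
    """
    raw = _parse_records(path, format)
    lengths = {len(r.residues) for r in raw}
    if len(lengths) != 1:
        raise UnequalLengthError(
            f"records in {path} differ in length: {sorted(lengths)}"
        )
    if alphabet is None:
        alphabet = detect_alphabet(raw)
    records = [SequenceRecord(r.id, _normalize(r.residues, alphabet)) for r in raw]
    return Alignment(records=records, query_id=query_id, alphabet=alphabet)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read unaligned FASTA sequences as an id -> residues mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"no sequences found in {path}")
    return out


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA (the pipeline's canonical output format)."""
    with open(path, "w") as fh:
        for rec in alignment.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def write_fasta(sequences: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def alignment_to_string(alignment: Alignment) -> str:
    buf = io.StringIO()
    for rec in alignment.records:
        buf.write(f">{rec.id}\n{rec.residues}\n")
    return buf.getvalue()


def build_query_map(alignment: Alignment) -> QueryPositionMap:
    """Columns of the MSA holding each non-gap query character, in order."""
    q = alignment.query.residues
    cols = tuple(i for i, c in enumerate(q) if c != GAP)
    return QueryPositionMap(msa_col_for_query_pos=cols)
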