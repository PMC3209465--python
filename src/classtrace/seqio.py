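"""Sequence and alignment I/O, pairwise identity, and domain-segment slicing.

Protein sequences and multiple sequence alignments are the substrate of the
trace analysis.  This module reads and writes FASTA and Clustal files
(through Biopython, with stricter validation on top), computes percent
identity between aligned rows under two explicit denominator conventions,
and slices an alignment down to the columns spanned by a residue interval of
a chosen reference row — the way a motor domain or neck region is excised
from a full-length alignment before tracing.

Conventions
-----------
* The only gap character is ``'-'``; ``'.'`` is normalised to ``'-'`` on
  read (with a warning).  Residues are stored uppercase.
* Reference residue numbering is 1-based over the ungapped reference
  sequence, matching PDB author numbering style ("Asp215").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP = "-"


class ParseError(ValueError):
    """A file could not be parsed into valid records."""


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with an identifier.

    ``residues`` is a string over the 20 amino acids plus ``X`` for unknown;
    gap characters are not allowed here (they are stripped on read).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An ordered set of equal-length aligned protein sequences.

    Invariants (enforced at construction): at least two rows, unique ids,
    all rows the same length, characters drawn from the amino-acid alphabet
    plus ``'-'``.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        ids = [rid for rid, _ in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sequence ids in alignment: {sorted(dupes)}")
        length = len(self.records[0][1])
        for rid, row in self.records:
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {length}"
                )
            bad = set(row) - ALPHABET - {GAP}
            if bad:
                raise ValueError(
                    f"alignment row {rid!r} contains invalid characters: {sorted(bad)}"
                )

    # -- container-ish helpers -------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def row(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(f"no row with id {rid!r}")

    def column(self, index: int) -> list[tuple[str, str]]:
        """Column ``index`` (1-based) as ``(id, residue)`` pairs."""
        if not 1 <= index <= self.n_columns:
            raise IndexError(f"column {index} outside 1..{self.n_columns}")
        return [(rid, row[index - 1]) for rid, row in self.records]

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        """Rows restricted to ``ids``, keeping original order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return AlignedSequenceSet(
            tuple((r, s) for r, s in self.records if r in wanted)
        )


@dataclass(frozen=True)
class SegmentSpec:
    """A residue interval on a reference row, naming a domain segment.

    ``ref_start``/``ref_end`` are 1-based inclusive positions in the
    *ungapped* reference sequence.
    """

    name: str
    ref_id: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise ValueError(
                f"invalid segment span {self.ref_start}..{self.ref_end}"
            )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _normalise(seq: str, rid: str, strip_gaps: bool) -> str:
    s = seq.upper()
    if "." in s:
        warnings.warn(f"sequence {rid!r}: '.' characters normalised to '-'")
        s = s.replace(".", GAP)
    if strip_gaps and GAP in s:
        warnings.warn(f"sequence {rid!r}: gap characters stripped")
        s = s.replace(GAP, "")
    return s


def read_sequences(path: str | Path, format: Literal["fasta"] = "fasta") -> list[SequenceRecord]:
    """Read ungapped sequences from a FASTA file, in file order.

    Gap characters found in the input are stripped with a warning.  An empty
    file or a file whose first non-blank line is not a FASTA header raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if format != "fasta":
        raise ValueError(f"unsupported sequence format: {format!r}")
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:40]!r}"
                )
            break
    else:
        raise ParseError(f"{path}: line 1: file contains no FASTA records")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalise(str(rec.seq), rec.id, strip_gaps=True),
                description=rec.description,
            )
        )
    if not records:
        raise ParseError(f"{path}: line 1: file contains no FASTA records")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, one record per ``>id description`` header."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(
    path: str | Path, format: Literal["fasta", "clustal"] = "fasta"
) -> AlignedSequenceSet:
    """Read a multiple sequence alignment from FASTA or Clustal ``.aln``.

    Raises :class:`ParseError` naming the offending id on ragged rows and on
    duplicate ids.
    """
    path = Path(path)
    if format == "fasta":
        rows = [(rec.id, _normalise(str(rec.seq), rec.id, strip_gaps=False))
                for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ParseError(f"{path}: not a valid Clustal alignment: {exc}") from exc
        rows = [(rec.id, _normalise(str(rec.seq), rec.id, strip_gaps=False))
                for rec in aln]
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if not rows:
        raise ParseError(f"{path}: no alignment rows found")
    length = len(rows[0][1])
    for rid, row in rows:
        if len(row) != length:
            raise ParseError(
                f"{path}: ragged alignment row {rid!r} "
                f"(length {len(row)}, expected {length})"
            )
    try:
        return AlignedSequenceSet(tuple(rows))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_alignment(
    msa: AlignedSequenceSet, path: str | Path,
    format: Literal["fasta", "clustal"] = "fasta",
) -> None:
    bio = [_BioSeqRecord(Seq(s), id=rid, description="") for rid, s in msa.records]
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in bio:
                fh.write(f">{rec.id}\n{rec.seq}\n")
    elif format == "clustal":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(bio), str(path), "clustal")
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

Denominator = Literal["aligned_columns_excluding_dual_gaps", "shorter_ungapped_length"]


def percent_identity(
    a: str, b: str,
    denominator: Denominator = "aligned_columns_excluding_dual_gaps",
) -> float:
    """Percent identity (0–100) between two equal-length aligned strings.

    A column counts as a match when both rows carry the same non-gap residue.
    The default denominator is the number of columns where at least one row
    has a residue; ``shorter_ungapped_length`` divides by the shorter of the
    two ungapped sequence lengths instead (a convention that ignores
    terminal-gap overhang).  Symmetric in its arguments.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned strings differ in length: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    if denominator == "aligned_columns_excluding_dual_gaps":
        denom = sum(1 for x, y in zip(a, b) if not (x == GAP and y == GAP))
    elif denominator == "shorter_ungapped_length":
        denom = min(len(a.replace(GAP, "")), len(b.replace(GAP, "")))
    else:
        raise ValueError(f"unknown denominator convention: {denominator!r}")
    if denom == 0:
        raise ValueError("percent identity undefined: zero comparable columns")
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# segment slicing
# ---------------------------------------------------------------------------

def reference_column_map(msa: AlignedSequenceSet, ref_id: str) -> dict[int, int]:
    """Map 1-based ungapped reference residue numbers to 1-based columns."""
    row = msa.row(ref_id)
    mapping: dict[int, int] = {}
    resno = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            resno += 1
            mapping[resno] = col
    return mapping


def slice_segment(
    msa: AlignedSequenceSet, spec: SegmentSpec
) -> tuple[AlignedSequenceSet, list[int]]:
    """Columns spanned by reference residues ``ref_start..ref_end``.

    Columns where the reference is gapped *inside* the span are retained
    (insertions relative to the reference stay with the segment).  Returns
    the sliced alignment and the list of original 1-based column indices.
    """
    if spec.ref_id not in msa.ids:
        raise KeyError(f"reference id {spec.ref_id!r} not in alignment")
    res2col = reference_column_map(msa, spec.ref_id)
    ungapped_len = len(res2col)
    if spec.ref_end > ungapped_len:
        raise ValueError(
            f"segment {spec.name!r} span {spec.ref_start}..{spec.ref_end} exceeds "
            f"reference length {ungapped_len}"
        )
    c0, c1 = res2col[spec.ref_start], res2col[spec.ref_end]
    columns = list(range(c0, c1 + 1))
    sliced = AlignedSequenceSet(
        tuple((rid, row[c0 - 1:c1]) for rid, row in msa.records)
    )
    return sliced, columns
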