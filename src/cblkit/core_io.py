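"""Sequence and table I/O shared by every pipeline stage.

Protein sequences travel as :class:`ProteinRecord`; gapped multiple
alignments as :class:`AlignmentBlock`.  All residue and column positions
are reported 1-based, counting the initiator Met as position 1, which is
how positions are quoted throughout the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "ProteinRecord",
    "AlignmentBlock",
    "OrfSummary",
    "AlphabetError",
    "AlignmentShapeError",
    "FrameError",
    "read_fasta",
    "write_fasta",
    "orf_to_protein_length",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""


class AlignmentShapeError(ValueError):
    """Alignment members do not all share the same length."""


class FrameError(ValueError):
    """An ORF length is not a whole number of codons, or is too short."""


def _validate_sequence(record_id: str, seq: str, allow_gaps: bool) -> None:
    if not seq:
        raise AlphabetError(f"record {record_id!r}: empty sequence")
    allowed = _AA_SET | {GAP} if allow_gaps else _AA_SET
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise AlphabetError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with species metadata.

    ``sequence`` is upper case over the 20 standard one-letter codes;
    ambiguity codes such as ``X`` or ``B`` are rejected outright so that
    composition and motif scanning stay well defined.  When the record is
    an alignment row the gap symbol ``-`` is additionally permitted.
    """

    id: str
    sequence: str
    genus: str = ""
    species_epithet: str = ""
    aligned: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_sequence(self.id, self.sequence, allow_gaps=self.aligned)

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapped multiple alignment of at least two protein sequences."""

    records: tuple[ProteinRecord, ...]
    n_columns: int = 0

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if len(records) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 members")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"unequal member lengths in alignment: {sorted(lengths)}"
            )
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "n_columns", lengths.pop())

    def __len__(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """1-based alignment column as a string, one character per member."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r.sequence[col - 1] for r in self.records)


@dataclass(frozen=True)
class OrfSummary:
    """Bookkeeping pair: ORF nucleotide count (stop included) and residue count."""

    orf_nt: int
    protein_aa: int

    def __post_init__(self) -> None:
        if self.orf_nt % 3:
            raise FrameError(f"ORF of {self.orf_nt} nt is not a whole number of codons")
        if self.protein_aa != self.orf_nt // 3 - 1 or self.protein_aa < 1:
            raise FrameError(
                f"inconsistent ORF summary: {self.orf_nt} nt vs {self.protein_aa} aa"
            )


def orf_to_protein_length(orf_nt: int) -> int:
    """Residues encoded by an ORF of ``orf_nt`` nucleotides (stop codon included).

    A 3048-nt ORF encodes 1015 residues; a 426-nt ORF encodes 141.
    """
    if orf_nt % 3:
        raise FrameError(f"ORF of {orf_nt} nt is not a whole number of codons")
    if orf_nt < 6:
        raise FrameError(f"ORF of {orf_nt} nt is too short to encode a protein")
    return orf_nt // 3 - 1


def _parse_header(description: str) -> str:
    return description.split()[0] if description.split() else description


def read_fasta(
    path: Union[str, Path], aligned: bool = False
) -> Union[list[ProteinRecord], AlignmentBlock]:
    """Read a FASTA file of protein sequences.

    With ``aligned=True`` the file is treated as a gapped multiple
    alignment and returned as an :class:`AlignmentBlock`; sequence lengths
    must then agree.  Record order is preserved; the identifier is the
    header up to the first whitespace.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=_parse_header(rec.description), sequence=str(rec.seq),
                          aligned=aligned)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if aligned:
        return AlignmentBlock(records=tuple(records))
    return records


def write_fasta(
    records: Union[Iterable[ProteinRecord], AlignmentBlock],
    path: Union[str, Path],
    wrap: int = 60,
) -> Path:
    """Write records to FASTA, wrapping sequence lines at ``wrap`` columns."""
    if isinstance(records, AlignmentBlock):
        records = records.records
    path = Path(path)
    seqio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seqio_records)
    return path


def records_to_block(records: Sequence[ProteinRecord]) -> AlignmentBlock:
    """Re-wrap equal-length records (possibly gapped) as an alignment block."""
    rows = tuple(
        ProteinRecord(id=r.id, sequence=r.sequence, genus=r.genus,
                      species_epithet=r.species_epithet, aligned=True)
        for r in records
    )
    return AlignmentBlock(records=rows)
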