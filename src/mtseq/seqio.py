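"""Sequence and region-annotation I/O.

All downstream analyses operate on :class:`SequenceRecord` collections read
from FASTA, optionally paired with per-transcript region annotations
(5'UTR / CDS / 3'UTR lengths) read from TSV.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* input is case-insensitive and uppercased on read;
* cDNA records are taken as the sense (mRNA) strand as given in the FASTA;
* DNA records may contain IUPAC ambiguity codes (``N`` etc.); such records
  are retained, but every counting window that overlaps an ambiguous
  position is skipped by the analysis modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "RegionAnnotation",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "reverse_complement",
]


class Alphabet(str, enum.Enum):
    DNA = "dna"
    PROTEIN = "protein"


#: Unambiguous DNA bases.
DNA_BASES = "ACGT"
#: IUPAC ambiguity codes accepted (skipped by counting windows downstream).
DNA_AMBIGUOUS = set("NRYSWKMBDHV")
#: The 20 standard amino acids.
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity letters tolerated in protein input (skipped by counting windows).
PROTEIN_AMBIGUOUS = set("XBZJUO*")

_DNA_OK = set(DNA_BASES) | DNA_AMBIGUOUS
_PROT_OK = PROTEIN_LETTERS | PROTEIN_AMBIGUOUS

class AlphabetError(ValueError):
    """Raised when a sequence violates its declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet."""

    id: str
    seq: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        validate_sequence(self.seq, self.alphabet, record_id=self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionAnnotation:
    """Per-transcript 5'UTR / CDS / 3'UTR lengths in nucleotides.

    The three lengths define three half-open intervals covering the
    transcript exactly once in 5'->3' order.
    """

    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        for name in ("utr5_len", "cds_len", "utr3_len"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValueError(
                    f"{self.transcript_id}: {name} must be a non-negative integer, got {v!r}"
                )

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    def intervals(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) intervals for UTR5, CDS, UTR3."""
        a = self.utr5_len
        b = a + self.cds_len
        c = b + self.utr3_len
        return {"UTR5": (0, a), "CDS": (a, b), "UTR3": (b, c)}

    def region_of(self, offset: int) -> str:
        """Region label of a 0-based transcript offset."""
        if offset < 0 or offset >= self.total_len:
            raise ValueError(
                f"offset {offset} outside transcript {self.transcript_id} "
                f"of length {self.total_len}"
            )
        if offset < self.utr5_len:
            return "UTR5"
        if offset < self.utr5_len + self.cds_len:
            return "CDS"
        return "UTR3"


def validate_sequence(seq: str, alphabet: Alphabet, record_id: str = "<seq>") -> None:
    """Check residues against the declared alphabet.

    Ambiguity codes are accepted (they are skipped downstream); anything
    else raises :class:`AlphabetError` naming the record and position.
    """
    ok = _DNA_OK if alphabet is Alphabet.DNA else _PROT_OK
    for i, ch in enumerate(seq):
        if ch not in ok:
            raise AlphabetError(
                f"record {record_id!r}: illegal {alphabet.value} residue "
                f"{ch!r} at position {i}"
            )


def is_unambiguous_dna(seq: str) -> bool:
    return all(ch in "ACGT" for ch in seq)


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Returns one record per entry, uppercased, in file order. Duplicate IDs
    are rejected; an empty file yields an empty list.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;":
            raise ValueError(f"{path}: malformed FASTA, line 1 does not start with '>'")
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, str(entry.seq).upper(), alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            if not rec.seq:
                fh.write("\n")


_REGION_COLUMNS = ["transcript_id", "utr5_len", "cds_len", "utr3_len"]


def read_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read a region-annotation TSV.

    Expects header columns ``transcript_id  utr5_len  cds_len  utr3_len``;
    '#'-prefixed comment lines are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    missing = [c for c in _REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing region columns {missing}")
    annotations = []
    for row in df.itertuples(index=False):
        annotations.append(
            RegionAnnotation(
                transcript_id=str(row.transcript_id),
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
            )
        )
    return annotations


def write_regions(annotations: Iterable[RegionAnnotation], path: str | Path) -> None:
    rows = [
        (a.transcript_id, a.utr5_len, a.cds_len, a.utr3_len) for a in annotations
    ]
    pd.DataFrame(rows, columns=_REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def check_annotation(record: SequenceRecord, annotation: RegionAnnotation) -> None:
    """Verify that an annotation's total length matches its transcript."""
    if annotation.total_len != len(record):
        raise ValueError(
            f"transcript {record.id!r}: annotated length {annotation.total_len} "
            f"!= sequence length {len(record)}"
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string (involution)."""
    up = seq.upper()
    bad = set(up) - _DNA_OK
    if bad:
        raise AlphabetError(
            f"reverse_complement requires DNA input; illegal characters {sorted(bad)}"
        )
    return str(Seq(up).reverse_complement())
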