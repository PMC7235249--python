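"""Sequence record types and FASTA I/O.

Protein and DNA records are the universal currency of every pipeline stage.
Sequences are normalized to uppercase on construction and validated against
their alphabet; FASTA round-trips go through Biopython's SeqIO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

#: the 20 canonical residues plus X (unknown)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
DNA_ALPHABET = frozenset("ACGTN")
SPACER_ALPHABET = frozenset("ACGT")


def _check_alphabet(seq: str, allowed: frozenset[str], what: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise InputError(f"{what} contains invalid characters: {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20 canonical residues plus X)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InputError(f"protein record {self.id!r} has an empty sequence")
        _check_alphabet(self.sequence, PROTEIN_ALPHABET, f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DnaRecord:
    """A named DNA sequence over A/C/G/T/N (N marks assembly gaps)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InputError(f"DNA record {self.id!r} has an empty sequence")
        _check_alphabet(self.sequence, DNA_ALPHABET, f"DNA {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpacerRecord:
    """A CRISPR spacer: unambiguous DNA, at least 15 nt, tied to its source array."""

    id: str
    sequence: str
    array_id: str = ""

    MIN_LENGTH = 15

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < self.MIN_LENGTH:
            raise InputError(
                f"spacer {self.id!r} is {len(self.sequence)} nt; "
                f"minimum is {self.MIN_LENGTH}"
            )
        _check_alphabet(self.sequence, SPACER_ALPHABET, f"spacer {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _strip_id(record: SeqRecord) -> str:
    """FASTA headers repeat the id at the front of the description."""
    desc = record.description
    if desc == record.id:
        return ""
    if desc.startswith(record.id + " "):
        return desc[len(record.id) + 1:]
    return desc


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=r.id, sequence=str(r.seq), description=_strip_id(r))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def read_dna_fasta(path: str | Path) -> list[DnaRecord]:
    return [
        DnaRecord(id=r.id, sequence=str(r.seq), description=_strip_id(r))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def read_spacer_fasta(path: str | Path) -> list[SpacerRecord]:
    """Spacer FASTA; the source array id may ride in the description."""
    return [
        SpacerRecord(id=r.id, sequence=str(r.seq), array_id=_strip_id(r))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord | DnaRecord | SpacerRecord],
                path: str | Path) -> None:
    seqs: Iterator[SeqRecord] = (
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=getattr(r, "description", "") or getattr(r, "array_id", ""))
        for r in records
    )
    SeqIO.write(seqs, str(path), "fasta")
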