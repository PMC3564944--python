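"""FASTA reading/writing (Biopython-backed), normalised to upper case."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..errors import FormatError, ValidationError

_ALPHABET = re.compile(r"^[ACGTN]+$")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}, stored upper-case."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"sequence {self.name!r} is empty")
        if not _ALPHABET.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValidationError(
                f"sequence {self.name!r} contains non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(stream: IO[str]) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str],
                width: int = 60) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records),
        stream, "fasta")
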