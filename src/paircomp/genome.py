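"""Genome container and FASTA round-trip.

A :class:`Genome` is an ordered, named collection of chromosome sequences
held as plain uppercase strings over the {A, C, G, T, N} alphabet.  All
internal coordinates are 0-based, half-open; 1-based coordinates appear
only in VCF-like and GFF-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered mapping of chromosome name -> sequence string."""

    chroms: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        return self.chroms[name][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        chroms = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = str(rec.seq).upper()
        return cls(chroms)

    def to_fasta(self, path: str | Path) -> None:
        """Write FASTA wrapped at 60 columns."""
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chroms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def validate(self) -> None:
        for name, seq in self.chroms.items():
            extra = set(seq) - VALID_BASES
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(extra)}"
                )
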