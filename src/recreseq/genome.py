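"""Reference genome container and DNA utilities.

All coordinates inside the package are 0-based, half-open.  Report-facing
objects (VCF/BED/TSV emitters, table rows) convert to 1-based inclusive at
the point of output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A/C/G/T -> 0/1/2/3; anything else (N, sentinel) -> 4, which mismatches
# every genomic base during verification.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA into uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


class GenomeError(ValueError):
    """Raised for malformed genomes or impossible genome configurations."""


@dataclass
class RepeatLocus:
    """Footprint of a tandem repeat array embedded in the reference."""

    chrom: str
    start: int          # 0-based start of the array in the reference
    unit_length: int
    copies: int

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.copies


@dataclass
class ReferenceGenome:
    """Ordered map of chromosome name -> uppercase DNA sequence.

    ``repeat_arrays`` is in-memory metadata recorded when tandem arrays are
    embedded at generation time; it is not part of the FASTA representation.
    """

    chromosomes: dict[str, str]
    repeat_arrays: list[RepeatLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise GenomeError(f"chromosome {name!r} has zero length")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_size(self) -> int:
        return sum(len(seq) for seq in self.chromosomes.values())

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def gc_fraction(self) -> float:
        gc = total = 0
        for seq in self.chromosomes.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        chromosomes = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not chromosomes:
            raise GenomeError(f"no sequences found in {path}")
        return cls(chromosomes)
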