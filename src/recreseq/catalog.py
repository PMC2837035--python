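"""Transposon family catalog.

A family is described by its canonical sequence, its length, the length of
its terminal inverted repeats (TIRs) and the positions of copies already
present in the reference genome.  The bundled synthetic factory builds
families with the geometry of the C. elegans DNA transposons Tc1 (1,610 bp
with 54-bp TIRs) and Tc2 (2,074 bp with perfect 24-bp TIRs); both insert at
a TA dinucleotide which is duplicated on insertion.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import BASES, revcomp


class CatalogError(ValueError):
    pass


@dataclass
class TransposonFamily:
    name: str
    sequence: str
    tir_length: int
    # (chrom, start) of element bodies present in the reference, 0-based.
    # The flanking TA target-site duplication sits immediately outside
    # [start, start + length).
    reference_copies: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tir_length > len(self.sequence) // 2:
            raise CatalogError(
                f"{self.name}: TIR length {self.tir_length} exceeds half of "
                f"element length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def has_perfect_tirs(self) -> bool:
        t = self.tir_length
        return self.sequence[:t] == revcomp(self.sequence[-t:])

    def terminus(self, which: str, window: int) -> str:
        """The first (5') or last (3') ``window`` bases of the canonical sequence."""
        if window > self.length:
            raise CatalogError(
                f"{self.name}: terminal window {window} exceeds element length {self.length}"
            )
        if which == "5'":
            return self.sequence[:window]
        if which == "3'":
            return self.sequence[-window:]
        raise ValueError(f"terminus must be 5' or 3', got {which!r}")


@dataclass
class TransposonCatalog:
    families: dict[str, TransposonFamily]

    def __getitem__(self, name: str) -> TransposonFamily:
        return self.families[name]

    def __iter__(self):
        return iter(self.families.values())

    @classmethod
    def synthetic(
        cls,
        specs: dict[str, tuple[int, int]] | None = None,
        seed: int = 0,
    ) -> "TransposonCatalog":
        """Build a catalog of random elements with perfect TIRs.

        ``specs`` maps family name -> (element length, TIR length); the
        default recreates the Tc1/Tc2 geometry.  Sequences are random DNA
        with the last ``tir`` bases forced to be the reverse complement of
        the first ``tir`` bases.
        """
        if specs is None:
            specs = {"Tc1": (1610, 54), "Tc2": (2074, 24)}
        rng = np.random.default_rng([int(seed), 0x7E])
        families = {}
        for name, (length, tir) in specs.items():
            body = "".join(
                BASES[i] for i in rng.integers(0, 4, size=length)
            )
            seq = body[: length - tir] + revcomp(body[:tir])
            families[name] = TransposonFamily(name=name, sequence=seq, tir_length=tir)
        return cls(families)

    # --- persistence: FASTA for sequences, TSV for metadata -------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(fam.sequence), id=fam.name, description="")
            for fam in self
        ]
        with open(outdir / "catalog.fa", "w") as fh:
            SeqIO.FastaIO.FastaWriter(fh, wrap=60).write_file(records)
        with open(outdir / "catalog.tsv", "w") as fh:
            fh.write("name\tlength\ttir_length\treference_copies\n")
            for fam in self:
                copies = ";".join(f"{c}:{s + 1}" for c, s in fam.reference_copies)
                fh.write(f"{fam.name}\t{fam.length}\t{fam.tir_length}\t{copies}\n")

    @classmethod
    def read(cls, indir: str | Path) -> "TransposonCatalog":
        indir = Path(indir)
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(indir / "catalog.fa"), "fasta")
        }
        families = {}
        with open(indir / "catalog.tsv") as fh:
            header = fh.readline()
            if not header.startswith("name\t"):
                raise CatalogError("malformed catalog.tsv header")
            for line in fh:
                name, length, tir, copies = line.rstrip("\n").split("\t")
                if name not in seqs:
                    raise CatalogError(f"{name} in catalog.tsv but not in catalog.fa")
                if int(length) != len(seqs[name]):
                    raise CatalogError(
                        f"{name}: declared length {length} != sequence length {len(seqs[name])}"
                    )
                ref_copies = []
                if copies:
                    for item in copies.split(";"):
                        chrom, start = item.rsplit(":", 1)
                        ref_copies.append((chrom, int(start) - 1))
                families[name] = TransposonFamily(
                    name=name,
                    sequence=seqs[name],
                    tir_length=int(tir),
                    reference_copies=ref_copies,
                )
        return cls(families)
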