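"""Gene models: exon/CDS/UTR intervals, feature annotation and synonymy.

Supports a minimal GFF3 subset (gene/exon/CDS features with ID/Parent
attributes, the same subset the writer emits) and BED12.  Annotation
categories use the precedence CDS ("exon") > UTR > intron > intergenic;
synonymy is decided by translating the affected codon under the standard
genetic code using the CDS frame and strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .genome import ReferenceGenome, revcomp


class GeneModelError(ValueError):
    pass


Interval = tuple[int, int]   # 0-based half-open


def _within(intervals: Iterable[Interval], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise GeneModelError(f"{self.gene_id}: CDS interval outside exons")
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def utrs(self) -> list[Interval]:
        """Exonic intervals outside the CDS."""
        out = []
        for xs, xe in self.exons:
            cut = [(max(xs, cs), min(xe, ce)) for cs, ce in self.cds
                   if cs < xe and xs < ce]
            cursor = xs
            for cs, ce in sorted(cut):
                if cursor < cs:
                    out.append((cursor, cs))
                cursor = ce
            if cursor < xe:
                out.append((cursor, xe))
        return out

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced CDS in translation orientation."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int | None:
        """Offset of a genomic position within the translated CDS, or None."""
        cum = 0
        genomic = None
        for s, e in self.cds:
            if s <= pos < e:
                genomic = cum + (pos - s)
                break
            cum += e - s
        if genomic is None:
            return None
        if self.strand == "-":
            return self.cds_length - 1 - genomic
        return genomic


def classify_position(
    pos: int, chrom: str, gene_models: Sequence[GeneModel]
) -> tuple[str, GeneModel | None]:
    """Annotation category at a 0-based position, with CDS > UTR > intron
    precedence across overlapping genes."""
    best = ("intergenic", None)
    rank = {"exon": 3, "UTR": 2, "intron": 1, "intergenic": 0}
    for gene in gene_models:
        if gene.chrom != chrom or not gene.start <= pos < gene.end:
            continue
        if _within(gene.cds, pos):
            cat = "exon"
        elif _within(gene.utrs, pos):
            cat = "UTR"
        else:
            cat = "intron"
        if rank[cat] > rank[best[0]]:
            best = (cat, gene)
    return best


_COMP = str.maketrans("ACGT", "TGCA")


def synonymy(
    gene: GeneModel, pos: int, ref_base: str, alt_base: str, genome: ReferenceGenome
) -> str:
    """"synonymous" or "non-synonymous" for a substitution inside the CDS."""
    offset = gene.cds_offset(pos)
    if offset is None:
        raise GeneModelError(f"position {pos} not inside the CDS of {gene.gene_id}")
    cds = gene.cds_sequence(genome)
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMP)
        alt_base = alt_base.translate(_COMP)
    if cds[offset] != ref_base:
        raise GeneModelError(
            f"{gene.gene_id}: CDS base {cds[offset]} at offset {offset} "
            f"does not match reference base {ref_base}"
        )
    ci = offset // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mutant = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    same = Seq(codon).translate() == Seq(mutant).translate()
    return "synonymous" if same else "non-synonymous"


def annotate_call(call, gene_models: Sequence[GeneModel], genome: ReferenceGenome):
    """Fill a VariantCall's annotation/synonymy/gene fields in place."""
    pos = call.pos - 1
    category, gene = classify_position(pos, call.chrom, gene_models)
    call.annotation = category
    call.gene = gene.gene_id if gene is not None else None
    if category == "exon" and gene is not None:
        call.synonymy = synonymy(gene, pos, call.ref, call.alt, genome)
    else:
        call.synonymy = "NA"
    return call


# --------------------------------------------------------------------------
# I/O: minimal GFF3 subset and BED12
# --------------------------------------------------------------------------

def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chrom}\trecreseq\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\trecreseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            phase = 0
            cds = g.cds if g.strand == "+" else g.cds[::-1]
            for s, e in cds:
                fh.write(
                    f"{g.chrom}\trecreseq\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tParent={g.gene_id}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GeneModelError(f"malformed GFF3 line: {line.strip()!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attr = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            iv = (int(start) - 1, int(end))
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise GeneModelError("gene feature without ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [], "cds": []}
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent")
                if parent not in genes:
                    raise GeneModelError(f"{ftype} with unknown Parent {parent!r}")
                genes[parent]["exons" if ftype == "exon" else "cds"].append(iv)
    return [
        GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                  exons=g["exons"], cds=g["cds"])
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise GeneModelError("BED12 requires 12 columns")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = [
                (max(s, thick_s), min(e, thick_e))
                for s, e in exons
                if s < thick_e and thick_s < e and max(s, thick_s) < min(e, thick_e)
            ]
            models.append(
                GeneModel(gene_id=name, chrom=chrom, strand=strand,
                          exons=exons, cds=cds)
            )
    return models


# --------------------------------------------------------------------------
# synthetic gene models (for annotation demos and recovery tests)
# --------------------------------------------------------------------------

def random_gene_models(
    genome: ReferenceGenome,
    n_genes: int,
    rng: np.random.Generator | int = 0,
    utr_length: int = 30,
) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes with UTRs on random strands.

    Exon/intron sizes are drawn in realistic compact-genome ranges; CDS
    length is forced to a multiple of 3.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng([int(rng), 0x6E])
    models = []
    occupied: dict[str, list[Interval]] = {n: [] for n in genome.names}
    names = genome.names
    attempts = 0
    while len(models) < n_genes and attempts < 200 * n_genes:
        attempts += 1
        chrom = names[int(rng.integers(len(names)))]
        L = len(genome[chrom])
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(120, 300, size=n_exons)
        intron_lens = rng.integers(100, 400, size=n_exons - 1)
        total = int(exon_lens.sum() + intron_lens.sum())
        if L < total + 2000:
            continue
        start = int(rng.integers(1000, L - total - 1000))
        if any(start < e and start + total > s for s, e in occupied[chrom]):
            continue
        exons = []
        cursor = start
        for i, el in enumerate(exon_lens):
            exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        strand = "+-"[int(rng.integers(2))]
        coding = int(exon_lens.sum()) - 2 * utr_length
        coding -= coding % 3
        if coding <= 0:
            continue
        # lay the CDS over the exons after the 5' UTR (transcript order)
        cds = []
        if strand == "+":
            skip, remaining = utr_length, coding
            for s, e in exons:
                length = e - s
                if skip >= length:
                    skip -= length
                    continue
                cs = s + skip
                skip = 0
                take = min(remaining, e - cs)
                if take > 0:
                    cds.append((cs, cs + take))
                    remaining -= take
        else:
            skip, remaining = utr_length, coding
            for s, e in exons[::-1]:
                length = e - s
                if skip >= length:
                    skip -= length
                    continue
                ce = e - skip
                skip = 0
                take = min(remaining, ce - s)
                if take > 0:
                    cds.append((ce - take, ce))
                    remaining -= take
        occupied[chrom].append((start, start + total))
        models.append(
            GeneModel(
                gene_id=f"gene{len(models) + 1}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
    if len(models) < n_genes:
        raise GeneModelError("could not place the requested number of genes")
    return models
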