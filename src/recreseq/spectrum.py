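"""Base-substitution calling and spectrum statistics.

Substitutions between a homozygous sample and the reference are called from
pileups of uniquely mapped reads, classified into the six nonstrand-specific
substitution classes (a change and its reverse complement share a class,
e.g. G>A and C>T are both "G:C to A:T"), and summarised per chromosome
together with transition/transversion (Ts/Tv) ratios and regional densities.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, encode

#: Six nonstrand-specific substitution classes, in conventional table order.
SPECTRUM_CLASSES = (
    "G:C to A:T",
    "A:T to T:A",
    "G:C to T:A",
    "A:T to G:C",
    "A:T to C:G",
    "G:C to C:G",
)

#: Transitions preserve purine/pyrimidine identity; the other four classes
#: are transversions.
TRANSITION_CLASSES = frozenset({"G:C to A:T", "A:T to G:C"})

#: The two strand-specific changes pooled by each class.
CLASS_CHANGES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "G:C to A:T": (("G", "A"), ("C", "T")),
    "A:T to T:A": (("A", "T"), ("T", "A")),
    "G:C to T:A": (("G", "T"), ("C", "A")),
    "A:T to G:C": (("A", "G"), ("T", "C")),
    "A:T to C:G": (("A", "C"), ("T", "G")),
    "G:C to C:G": (("G", "C"), ("C", "G")),
}

_CHANGE_TO_CLASS = {
    change: label for label, changes in CLASS_CHANGES.items() for change in changes
}


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Map a strand-specific base change onto its nonstrand-specific class.

    classify(x -> y) == classify(complement(x) -> complement(y)) by
    construction, so the twelve ordered changes collapse onto six labels.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError(f"reference and alternate base are identical: {ref_base}")
    try:
        return _CHANGE_TO_CLASS[(ref_base, alt_base)]
    except KeyError:
        raise ValueError(f"not a substitution over ACGT: {ref_base}>{alt_base}") from None


def ts_tv_ratio(class_counts: Mapping[str, int]) -> float:
    """Transition/transversion ratio of a six-class count vector.

    Returns ``nan`` when there are no transversions (undefined ratio).
    """
    ts = sum(n for c, n in class_counts.items() if c in TRANSITION_CLASSES)
    tv = sum(n for c, n in class_counts.items() if c not in TRANSITION_CLASSES)
    if tv == 0:
        return float("nan")
    return ts / tv


def format_ratio(value: float) -> str:
    """Render a ratio the way mutation-spectrum tables conventionally do:
    two decimals with trailing zeros stripped (2.10 -> "2.1", 1.07 -> "1.07").
    """
    if np.isnan(value):
        return "NA"
    text = f"{value:.2f}"
    if text.endswith("0"):
        text = text[:-1]
    return text


@dataclass
class VariantCall:
    """A called base substitution (positions are 1-based for reporting)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_depth: int
    depth: int
    spectrum_class: str
    annotation: str | None = None      # exon / UTR / intron / intergenic
    synonymy: str | None = None        # synonymous / non-synonymous / NA
    gene: str | None = None


def pileup_consensus(
    alignments: Iterable,
    ref: ReferenceGenome,
    min_depth: int = 4,
    min_fraction: float = 0.8,
) -> list[VariantCall]:
    """Call homozygous substitutions from a pileup of uniquely mapped reads.

    A site is called when total depth >= ``min_depth`` and the most frequent
    non-reference base accounts for at least ``min_fraction`` of the depth.
    Multi-mapped and unmapped reads contribute nothing; zero-depth sites are
    skipped.
    """
    from .genome import revcomp  # local import to keep module load light

    names = ref.names
    chrom_index = {n: i for i, n in enumerate(names)}
    per_chrom_pos: list[list[np.ndarray]] = [[] for _ in names]
    per_chrom_code: list[list[np.ndarray]] = [[] for _ in names]
    offsets = None

    for pet in alignments:
        for half in (pet.r1, pet.r2):
            if half.status != "unique" or half.seq is None:
                continue
            seq = half.seq if half.strand == "+" else revcomp(half.seq)
            codes = encode(seq)
            n = len(codes)
            if offsets is None or len(offsets) != n:
                offsets = np.arange(n)
            ci = chrom_index[half.chrom]
            per_chrom_pos[ci].append(half.pos + offsets)
            per_chrom_code[ci].append(codes)

    calls: list[VariantCall] = []
    for ci, name in enumerate(names):
        if not per_chrom_pos[ci]:
            continue
        L = len(ref[name])
        pos = np.concatenate(per_chrom_pos[ci])
        code = np.concatenate(per_chrom_code[ci]).astype(np.int64)
        ok = code < 4
        counts = np.bincount(code[ok] * L + pos[ok], minlength=4 * L).reshape(4, L)
        depth = counts.sum(axis=0)
        refcodes = encode(ref[name]).astype(np.int64)
        cols = np.arange(L)
        nonref = counts.copy()
        nonref[refcodes, cols] = -1
        alt_code = nonref.argmax(axis=0)
        alt_depth = nonref[alt_code, cols]
        callable_ = (
            (depth >= min_depth)
            & (alt_depth > 0)
            & (alt_depth >= min_fraction * depth)
            & (refcodes < 4)
        )
        for p in np.nonzero(callable_)[0]:
            rb = "ACGT"[refcodes[p]]
            ab = "ACGT"[alt_code[p]]
            calls.append(
                VariantCall(
                    chrom=name,
                    pos=int(p) + 1,
                    ref=rb,
                    alt=ab,
                    alt_depth=int(alt_depth[p]),
                    depth=int(depth[p]),
                    spectrum_class=classify_substitution(rb, ab),
                )
            )
    return calls


class SpectrumTable:
    """Six-class x chromosome count matrix with derived totals and Ts/Tv.

    Mirrors the layout of per-chromosome substitution tables: one row per
    class, one column per chromosome, plus a Total column/row and a Ts/Tv
    row.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.reindex(index=list(SPECTRUM_CLASSES)).fillna(0).astype(int)
        self.counts = counts

    @classmethod
    def from_calls(
        cls, calls: Sequence[VariantCall], chromosomes: Sequence[str] | None = None
    ) -> "SpectrumTable":
        if chromosomes is None:
            chromosomes = sorted({c.chrom for c in calls})
        counts = pd.DataFrame(
            0, index=list(SPECTRUM_CLASSES), columns=list(chromosomes), dtype=int
        )
        for call in calls:
            if call.chrom in counts.columns:
                counts.loc[call.spectrum_class, call.chrom] += 1
        return cls(counts)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.counts.columns)

    def class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def chromosome_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def ts_tv(self, chrom: str | None = None) -> float:
        col = self.class_totals() if chrom is None else self.counts[chrom]
        return ts_tv_ratio(col.to_dict())

    def ts_tv_row(self) -> dict[str, float]:
        row = {chrom: self.ts_tv(chrom) for chrom in self.chromosomes}
        row["Total"] = self.ts_tv()
        return row

    def to_frame(self) -> pd.DataFrame:
        """Full display table: counts, Total row/column and formatted Ts/Tv."""
        table = self.counts.copy()
        table["Total"] = self.class_totals()
        totals = table.sum(axis=0)
        table = table.astype(object)
        table.loc["Total"] = totals
        table.loc["Ts/Tv"] = {
            k: format_ratio(v) for k, v in self.ts_tv_row().items()
        }
        return table

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="Base-difference")


def build_spectrum(
    calls: Sequence[VariantCall], genome: ReferenceGenome | Sequence[str]
) -> SpectrumTable:
    """Tabulate classified calls per chromosome into a SpectrumTable."""
    if isinstance(genome, ReferenceGenome):
        chromosomes = genome.names
    else:
        chromosomes = list(genome)
    return SpectrumTable.from_calls(calls, chromosomes)


def read_region_map(path) -> pd.DataFrame:
    """Read a 4-column TSV region map: chrom, start, end, label (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "label"], comment="#"
    )
    return df


def regional_density(
    calls: Sequence[VariantCall], region_map: pd.DataFrame
) -> pd.DataFrame:
    """Substitution density (differences per Mbp of region span) per region label.

    ``region_map`` needs columns chrom/start/end/label with 0-based half-open
    intervals that do not overlap within a chromosome.
    """
    for chrom, group in region_map.groupby("chrom"):
        intervals = group.sort_values("start")[["start", "end"]].to_numpy()
        if np.any(intervals[1:, 0] < intervals[:-1, 1]):
            raise ValueError(f"overlapping region intervals on {chrom}")
    spans = region_map.assign(span=lambda d: d.end - d.start).groupby("label")["span"].sum()
    if (spans == 0).any():
        zero = spans.index[spans == 0].tolist()
        raise ValueError(f"zero-span region label(s): {zero}")
    counts = dict.fromkeys(spans.index, 0)
    rows = region_map.to_records(index=False)
    for call in calls:
        p = call.pos - 1
        for chrom, start, end, label in rows:
            if chrom == call.chrom and start <= p < end:
                counts[label] += 1
                break
    out = pd.DataFrame(
        {
            "count": pd.Series(counts),
            "span_mbp": spans / 1e6,
        }
    )
    out["per_mbp"] = out["count"] / out["span_mbp"]
    return out


@dataclass
class RunSummary:
    total_reads: int
    aligned_reads: int
    read_length: int
    genome_size: int

    @property
    def percent_aligned(self) -> int:
        return round(100 * self.aligned_reads / self.total_reads)

    @property
    def fold_coverage(self) -> int:
        return round(self.aligned_reads * self.read_length / self.genome_size)


def run_summary(
    total_reads: int, aligned_reads: int, read_length: int, genome_size: int
) -> RunSummary:
    """Percent of reads aligned and fold sequence coverage, both rounded."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if aligned_reads > total_reads:
        raise ValueError("aligned reads exceed total reads")
    return RunSummary(total_reads, aligned_reads, read_length, genome_size)


def write_vcf(calls: Sequence[VariantCall], ref: ReferenceGenome, path) -> None:
    """Emit substitution calls as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=recreseq\n")
        for name, length in ref.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Substitution class">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Feature annotation">\n')
        fh.write('##INFO=<ID=SYN,Number=1,Type=String,Description="Synonymy">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = [
                f"CLASS={c.spectrum_class.replace(' ', '_')}",
                f"DP={c.depth}",
                f"AD={c.alt_depth}",
            ]
            if c.annotation:
                info.append(f"ANN={c.annotation}")
            if c.synonymy:
                info.append(f"SYN={c.synonymy}")
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{';'.join(info)}\n"
            )
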