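"""Ungapped short-read mapping by pigeonhole seeding.

Reads are aligned to the reference allowing at most ``max_mismatches``
Hamming mismatches and no indels.  Each read is split into
``max_mismatches + 1`` disjoint exact seeds; any alignment within the
mismatch budget must contain at least one exact seed, so exact k-mer lookup
of every seed followed by full-read Hamming verification enumerates all
valid loci.  The implementation is vectorised over read batches: seed codes
are resolved against a sorted k-mer table with binary search and candidate
windows are verified with one array comparison.

A read maps "unique" when exactly one locus attains the best distance,
"multi" otherwise, and "unmapped" when no locus is within budget.  N bases
mismatch everything.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pysam

from .genome import ReferenceGenome, encode, revcomp

_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class MappingError(ValueError):
    pass


class Alignment(NamedTuple):
    chrom: str
    pos: int            # 0-based leftmost
    strand: str         # '+' or '-'
    mismatches: int


@dataclass(slots=True)
class ReadHalf:
    """Mapping outcome of one mate."""

    status: str                  # unique / multi / unmapped
    chrom: str | None
    pos: int                     # 0-based leftmost; -1 if unmapped
    strand: str                  # '+', '-' or '.'
    mismatches: int              # -1 if unmapped
    seq: str                     # the read as sequenced


@dataclass(slots=True)
class PetAlignment:
    """One read pair's mapped coordinates and apparent fragment span.

    ``span`` (rightmost end - leftmost start) is defined only for proper
    pairs: both mates on one chromosome, opposite strands, inward
    orientation.
    """

    pair_id: str
    r1: ReadHalf
    r2: ReadHalf
    proper: bool
    span: int | None

    @property
    def chrom(self) -> str | None:
        return self.r1.chrom if self.r1.chrom is not None else self.r2.chrom

    def inner_interval(self, read_length: int) -> tuple[int, int] | None:
        """Interval between the facing read ends of a proper pair."""
        if not self.proper:
            return None
        left = min(self.r1.pos, self.r2.pos) + read_length
        right = max(self.r1.pos, self.r2.pos)
        return (min(left, right), max(left, right))


class GenomeIndex:
    """Exact k-mer lookup table over the forward strand of the genome.

    Chromosomes are concatenated with k sentinel characters between them;
    windows containing a sentinel or N are excluded.  Reverse-strand hits
    are found by searching the reverse complement of the query.
    """

    def __init__(self, genome: ReferenceGenome, k: int = 14):
        if k < 8:
            raise MappingError("seed length must be >= 8")
        if k > 31:
            raise MappingError("seed length must be <= 31")
        self.k = k
        self.genome = genome
        self.chrom_names = genome.names
        parts = []
        starts = []
        offset = 0
        sentinel = np.full(k, 4, dtype=np.uint8)
        for i, name in enumerate(self.chrom_names):
            if i > 0:
                parts.append(sentinel)
                offset += k
            codes = encode(genome[name])
            starts.append(offset)
            parts.append(codes)
            offset += len(codes)
        self.codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.chrom_starts = np.array(starts, dtype=np.int64)
        self.chrom_ends = self.chrom_starts + np.array(
            [len(genome[n]) for n in self.chrom_names], dtype=np.int64
        )
        self._powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        L = len(self.codes)
        if L >= k:
            windows = np.lib.stride_tricks.sliding_window_view(self.codes, k)
            codes64 = windows.astype(np.int64) @ self._powers
            valid = (windows < 4).all(axis=1)
            pos = np.nonzero(valid)[0]
            kmers = codes64[pos]
            order = np.argsort(kmers, kind="stable")
            self.sorted_kmers = kmers[order]
            self.sorted_pos = pos[order]
        else:
            self.sorted_kmers = np.empty(0, np.int64)
            self.sorted_pos = np.empty(0, np.int64)

    # ------------------------------------------------------------------
    def encode_kmer(self, kmer: str) -> int:
        codes = encode(kmer)
        if (codes > 3).any():
            return -1
        return int(codes.astype(np.int64) @ self._powers)

    def lookup(self, code: int) -> np.ndarray:
        """Global forward-strand positions of a k-mer code."""
        lo = np.searchsorted(self.sorted_kmers, code, side="left")
        hi = np.searchsorted(self.sorted_kmers, code, side="right")
        return self.sorted_pos[lo:hi]

    def positions(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (chrom, pos, strand) occurrences of ``kmer``.

        A reverse-strand occurrence means the reverse complement of the
        k-mer appears on the forward strand at that position; palindromic
        k-mers therefore report each locus on both strands.
        """
        if len(kmer) != self.k:
            raise MappingError(f"query length {len(kmer)} != index k {self.k}")
        out = []
        for strand, query in (("+", kmer), ("-", revcomp(kmer))):
            code = self.encode_kmer(query)
            if code < 0:
                continue
            for gpos in self.lookup(code):
                chrom, pos = self.to_chrom(int(gpos))
                out.append((chrom, pos, strand))
        return out

    def to_chrom(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_starts, gpos, side="right")) - 1
        return self.chrom_names[ci], gpos - int(self.chrom_starts[ci])

    def to_global(self, chrom: str, pos: int) -> int:
        ci = self.chrom_names.index(chrom)
        return int(self.chrom_starts[ci]) + pos


# --------------------------------------------------------------------------
# batch alignment core
# --------------------------------------------------------------------------

def _encode_batch(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), np.uint8)
    rl = len(seqs[0])
    buf = "".join(seqs).encode("ascii")
    flat = np.frombuffer(buf, dtype=np.uint8)
    if len(flat) != rl * len(seqs):
        raise MappingError("reads in a batch must share one length")
    from .genome import _ENCODE
    return _ENCODE[flat].reshape(len(seqs), rl)


def _candidate_hits(
    mat: np.ndarray, index: GenomeIndex, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All verified hits for a batch of same-length reads.

    Returns parallel arrays (read_idx, global_pos, strand, mismatches)
    sorted by (read_idx, mismatches, global_pos, strand).
    """
    N, rl = mat.shape
    k = index.k
    nseeds = max_mismatches + 1
    if nseeds * k > rl:
        raise MappingError(
            f"read length {rl} too short for {nseeds} disjoint {k}-mers"
        )
    offsets = [i * k for i in range(nseeds)]
    powers = index._powers

    cand_read = []
    cand_pos = []
    cand_strand = []
    for strand_code, oriented in ((0, mat), (1, _RC_CODE[mat[:, ::-1]])):
        for off in offsets:
            window = oriented[:, off : off + k]
            codes = window.astype(np.int64) @ powers
            codes[(window > 3).any(axis=1)] = -1
            lo = np.searchsorted(index.sorted_kmers, codes, side="left")
            hi = np.searchsorted(index.sorted_kmers, codes, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            reads = np.repeat(np.arange(N), counts)
            base = np.repeat(lo, counts)
            shift = np.arange(total) - np.repeat(
                np.concatenate(([0], np.cumsum(counts)[:-1])), counts
            )
            gpos = index.sorted_pos[base + shift] - off
            cand_read.append(reads)
            cand_pos.append(gpos)
            cand_strand.append(np.full(total, strand_code, dtype=np.int8))

    if not cand_read:
        empty = np.empty(0, np.int64)
        return empty, empty, empty.astype(np.int8), empty

    read_idx = np.concatenate(cand_read)
    gpos = np.concatenate(cand_pos)
    strand = np.concatenate(cand_strand)

    # bounds: the full window must sit inside one chromosome
    ci = np.searchsorted(index.chrom_starts, gpos, side="right") - 1
    ci = np.clip(ci, 0, len(index.chrom_starts) - 1)
    ok = (gpos >= index.chrom_starts[ci]) & (gpos + rl <= index.chrom_ends[ci])
    read_idx, gpos, strand = read_idx[ok], gpos[ok], strand[ok]

    # deduplicate (a locus may be reached through several seeds)
    span = len(index.codes) + 1
    key = (read_idx * 2 + strand) * span + gpos
    _, first = np.unique(key, return_index=True)
    read_idx, gpos, strand = read_idx[first], gpos[first], strand[first]

    # verify with a full Hamming comparison
    mism = np.empty(len(gpos), dtype=np.int64)
    chunk = 1 << 18
    win_off = np.arange(rl)
    rc_mat = _RC_CODE[mat[:, ::-1]]
    for s in range(0, len(gpos), chunk):
        e = min(s + chunk, len(gpos))
        windows = index.codes[gpos[s:e, None] + win_off]
        rows = np.where(
            (strand[s:e] == 0)[:, None], mat[read_idx[s:e]], rc_mat[read_idx[s:e]]
        )
        mism[s:e] = (windows != rows).sum(axis=1)
    ok = mism <= max_mismatches
    read_idx, gpos, strand, mism = read_idx[ok], gpos[ok], strand[ok], mism[ok]

    order = np.lexsort((strand, gpos, mism, read_idx))
    return read_idx[order], gpos[order], strand[order], mism[order]


@dataclass
class BatchHits:
    """Hits of a read batch grouped per read."""

    read_idx: np.ndarray
    gpos: np.ndarray
    strand: np.ndarray
    mismatches: np.ndarray
    n_reads: int
    group_start: np.ndarray   # n_reads + 1 offsets into the hit arrays

    @classmethod
    def collect(cls, arrays, n_reads: int) -> "BatchHits":
        read_idx, gpos, strand, mism = arrays
        bounds = np.searchsorted(read_idx, np.arange(n_reads + 1))
        return cls(read_idx, gpos, strand, mism, n_reads, bounds)

    def hits_of(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e = self.group_start[i], self.group_start[i + 1]
        return self.gpos[s:e], self.strand[s:e], self.mismatches[s:e]

    def best_of(self, i: int) -> tuple[np.ndarray, np.ndarray, int, int]:
        """(positions, strands, best_mm, n_best); hits are mm-sorted."""
        gpos, strand, mism = self.hits_of(i)
        if len(gpos) == 0:
            return gpos, strand, -1, 0
        best = int(mism[0])
        n_best = int(np.searchsorted(mism, best, side="right"))
        return gpos[:n_best], strand[:n_best], best, n_best


def align_batch(
    seqs: Sequence[str], index: GenomeIndex, max_mismatches: int = 2
) -> BatchHits:
    mat = _encode_batch(seqs)
    if mat.size == 0:
        empty = np.empty(0, np.int64)
        return BatchHits(empty, empty, empty.astype(np.int8), empty, 0,
                         np.zeros(1, np.int64))
    return BatchHits.collect(
        _candidate_hits(mat, index, max_mismatches), len(seqs)
    )


# --------------------------------------------------------------------------
# public single/pair interfaces
# --------------------------------------------------------------------------

@dataclass
class SingleReadResult:
    status: str                  # unique / multi / unmapped
    alignments: list[Alignment]  # all loci within the mismatch budget

    @property
    def best(self) -> Alignment | None:
        return self.alignments[0] if self.alignments else None


def map_single(
    read: str, index: GenomeIndex, max_mismatches: int = 2
) -> SingleReadResult:
    """All alignments of one read within the mismatch budget.

    Status is "unique" if exactly one locus attains the best distance,
    "multi" if several do, "unmapped" if no locus is within budget.
    """
    hits = align_batch([read.upper()], index, max_mismatches)
    gpos, strand, mism = hits.hits_of(0)
    alignments = [
        Alignment(index.to_chrom(int(g))[0], index.to_chrom(int(g))[1],
                  "+-"[int(s)], int(m))
        for g, s, m in zip(gpos, strand, mism)
    ]
    if not alignments:
        return SingleReadResult("unmapped", [])
    best = alignments[0].mismatches
    n_best = sum(1 for a in alignments if a.mismatches == best)
    return SingleReadResult("unique" if n_best == 1 else "multi", alignments)


_MULTI_CAP = 16


def _resolve_pair(
    i: int,
    seq1: str,
    seq2: str,
    hits1: BatchHits,
    hits2: BatchHits,
    index: GenomeIndex,
    rl: int,
    expected_span: float,
    pair_id: str,
) -> PetAlignment:
    g1, s1, m1, n1 = hits1.best_of(i)
    g2, s2, m2, n2 = hits2.best_of(i)
    status1 = "unmapped" if n1 == 0 else ("unique" if n1 == 1 else "multi")
    status2 = "unmapped" if n2 == 0 else ("unique" if n2 == 1 else "multi")

    def half(status, gpos, strand, mm, seq) -> ReadHalf:
        if status == "unmapped" or gpos is None:
            return ReadHalf(status, None, -1, ".", -1, seq)
        chrom, pos = index.to_chrom(int(gpos))
        return ReadHalf(status, chrom, pos, "+-"[int(strand)], int(mm), seq)

    chosen1 = 0 if n1 == 1 else None
    chosen2 = 0 if n2 == 1 else None
    if n1 and n2 and (n1 > 1 or n2 > 1) and max(n1, n2) <= _MULTI_CAP:
        # one or both mates are multi-mapped: among proper combinations of
        # best-distance loci, pick the one whose span is closest to the
        # expected span, provided the minimizer is unique
        best_combo = None
        best_delta = None
        ties = False
        for a in range(n1):
            for b in range(n2):
                if s1[a] == s2[b]:
                    continue
                plus_g, minus_g = (g1[a], g2[b]) if s1[a] == 0 else (g2[b], g1[a])
                if plus_g > minus_g:
                    continue
                span = int(minus_g) + rl - int(plus_g)
                delta = abs(span - expected_span)
                if best_delta is None or delta < best_delta - 1e-9:
                    best_delta, best_combo, ties = delta, (a, b), False
                elif abs(delta - best_delta) <= 1e-9:
                    ties = True
        if best_combo is not None and not ties:
            chosen1, chosen2 = best_combo

    r1 = half(status1, g1[chosen1] if chosen1 is not None else None,
              s1[chosen1] if chosen1 is not None else 0,
              m1 if chosen1 is not None else -1, seq1)
    r2 = half(status2, g2[chosen2] if chosen2 is not None else None,
              s2[chosen2] if chosen2 is not None else 0,
              m2 if chosen2 is not None else -1, seq2)

    proper = False
    span = None
    if (
        r1.chrom is not None
        and r2.chrom is not None
        and r1.chrom == r2.chrom
        and r1.strand != r2.strand
        and r1.strand in "+-"
        and r2.strand in "+-"
    ):
        plus, minus = (r1, r2) if r1.strand == "+" else (r2, r1)
        if plus.pos <= minus.pos:
            proper = True
            span = minus.pos + rl - plus.pos
    return PetAlignment(pair_id, r1, r2, proper, span)


def map_pair(
    r1: str,
    r2: str,
    index: GenomeIndex,
    max_mismatches: int = 2,
    expected_span: float = 200.0,
) -> PetAlignment:
    """Map one read pair; see :func:`map_read_pairs` for batch mapping."""
    hits1 = align_batch([r1.upper()], index, max_mismatches)
    hits2 = align_batch([r2.upper()], index, max_mismatches)
    return _resolve_pair(
        0, r1.upper(), r2.upper(), hits1, hits2, index,
        len(r1), expected_span, "pair0"
    )


def map_read_pairs(
    reads,
    index: GenomeIndex,
    max_mismatches: int = 2,
    expected_span: float = 200.0,
    batch_size: int = 200_000,
) -> list[PetAlignment]:
    """Map all pairs of a :class:`~recreseq.simulate.PairedReads` set."""
    out: list[PetAlignment] = []
    n = len(reads.r1)
    rl = len(reads.r1[0]) if n else 0
    for s in range(0, n, batch_size):
        e = min(s + batch_size, n)
        batch1 = [r.upper() for r in reads.r1[s:e]]
        batch2 = [r.upper() for r in reads.r2[s:e]]
        hits1 = align_batch(batch1, index, max_mismatches)
        hits2 = align_batch(batch2, index, max_mismatches)
        for i in range(e - s):
            out.append(
                _resolve_pair(
                    i, batch1[i], batch2[i], hits1, hits2, index, rl,
                    expected_span, f"pair{s + i}",
                )
            )
    return out


# --------------------------------------------------------------------------
# SAM input/output
# --------------------------------------------------------------------------

_STATUS_TAG = {"unique": "U", "multi": "R", "unmapped": "N"}
_TAG_STATUS = {v: k for k, v in _STATUS_TAG.items()}


def write_sam(
    alignments: Iterable[PetAlignment], genome: ReferenceGenome, path
) -> None:
    """Write pairs as SAM 1.x; the NM tag carries the mismatch count and the
    XT tag the unique/multi/unmapped status."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": L} for n, L in genome.lengths.items()],
    }
    ref_ids = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pet in alignments:
            halves = (pet.r1, pet.r2)
            for which, half in enumerate(halves):
                mate = halves[1 - which]
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = pet.pair_id
                flag = 0x1 | (0x40 if which == 0 else 0x80)
                mapped = half.status != "unmapped" and half.chrom is not None
                mate_mapped = mate.status != "unmapped" and mate.chrom is not None
                if not mapped:
                    flag |= 0x4
                if not mate_mapped:
                    flag |= 0x8
                if mapped and half.strand == "-":
                    flag |= 0x10
                if mate_mapped and mate.strand == "-":
                    flag |= 0x20
                if pet.proper:
                    flag |= 0x2
                seg.flag = flag
                if mapped:
                    seg.reference_id = ref_ids[half.chrom]
                    seg.reference_start = half.pos
                    seg.cigarstring = f"{len(half.seq)}M"
                    seg.mapping_quality = 60 if half.status == "unique" else 0
                    seg.query_sequence = (
                        half.seq if half.strand == "+" else revcomp(half.seq)
                    )
                elif mate_mapped:
                    # SAM convention: place an unmapped mate at its mate
                    seg.reference_id = ref_ids[mate.chrom]
                    seg.reference_start = mate.pos
                    seg.query_sequence = half.seq
                else:
                    seg.reference_id = -1
                    seg.reference_start = -1
                    seg.query_sequence = half.seq
                if mate_mapped:
                    seg.next_reference_id = ref_ids[mate.chrom]
                    seg.next_reference_start = mate.pos
                elif mapped:
                    seg.next_reference_id = ref_ids[half.chrom]
                    seg.next_reference_start = half.pos
                else:
                    seg.next_reference_id = -1
                    seg.next_reference_start = -1
                if pet.proper and pet.span is not None and mapped:
                    seg.template_length = pet.span if half.strand == "+" else -pet.span
                else:
                    seg.template_length = 0
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(half.seq)
                )
                tags = [("XT", _STATUS_TAG[half.status])]
                if mapped and half.mismatches >= 0:
                    tags.append(("NM", half.mismatches))
                seg.set_tags(tags)
                out.write(seg)


def read_sam(path) -> list[PetAlignment]:
    """Parse a SAM file produced by :func:`write_sam` (or compatible) back
    into PetAlignments."""
    pairs: dict[str, dict[int, ReadHalf]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            mapped = not seg.is_unmapped
            if mapped:
                chrom = seg.reference_name
                if seg.reference_end is not None and seg.reference_end > lengths.get(
                    chrom, 0
                ):
                    raise MappingError(
                        f"record {seg.query_name}: coordinates beyond {chrom} length"
                    )
            if seg.has_tag("XT"):
                status = _TAG_STATUS[seg.get_tag("XT")]
            else:
                status = "unique" if mapped else "unmapped"
            seq = seg.query_sequence or ""
            if mapped and seg.is_reverse:
                seq = revcomp(seq)
            half = ReadHalf(
                status=status,
                chrom=seg.reference_name if mapped else None,
                pos=seg.reference_start if mapped else -1,
                strand=("-" if seg.is_reverse else "+") if mapped else ".",
                mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else -1,
                seq=seq,
            )
            name = seg.query_name
            if name not in pairs:
                pairs[name] = {}
                order.append(name)
            pairs[name][1 if seg.is_read2 else 0] = half

    out = []
    for name in order:
        halves = pairs[name]
        r1 = halves.get(0) or ReadHalf("unmapped", None, -1, ".", -1, "")
        r2 = halves.get(1) or ReadHalf("unmapped", None, -1, ".", -1, "")
        proper = False
        span = None
        if (
            r1.chrom is not None
            and r1.chrom == r2.chrom
            and r1.strand != r2.strand
            and r1.strand in "+-"
            and r2.strand in "+-"
        ):
            plus, minus = (r1, r2) if r1.strand == "+" else (r2, r1)
            if plus.pos <= minus.pos:
                proper = True
                span = minus.pos + len(minus.seq) - plus.pos
        out.append(PetAlignment(name, r1, r2, proper, span))
    return out
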