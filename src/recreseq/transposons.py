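"""Transposon insertion detection from paired-end terminus evidence.

The algorithm finds read pairs in which one mate (the *anchor*) maps
uniquely to the genome while the other matches one of the terminal windows
(default 300 bp) of a canonical transposon sequence.  Anchors are grouped
into same-strand clusters; an insertion is marked by a forward-strand
cluster upstream and a reverse-strand cluster downstream.  The separation
between the two clusters distinguishes element copies already present in
the reference (separation ~ element length + fragment size) from novel
insertions (separation ~ fragment size, i.e. about 200-300 bp for a
180-220 bp library).  For novel sites, the TA target dinucleotide between
the innermost reads gives the base-exact insertion point; Tc1/Tc2-family
elements insert into TA and duplicate it, so a confirmed call requires
exactly one TA candidate in the inter-cluster gap.  An excision (empty
site) search scans unmapped reads for the joined flanking sequence of known
element copies with a TA or TATA footprint.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog import CatalogError, TransposonCatalog, TransposonFamily
from .genome import ReferenceGenome, encode, revcomp
from .genes import GeneModel, classify_position
from .mapping import PetAlignment


class TEDetectionError(ValueError):
    pass


@dataclass(slots=True)
class TerminusHit:
    """A uniquely mapped anchor whose mate matches a transposon terminus."""

    family: str
    terminus: str          # "5'" or "3'"
    chrom: str
    anchor_pos: int        # 0-based leftmost of the anchor read
    anchor_strand: str
    anchor_end: int
    mate_offset: int       # offset of the mate within the terminal window
    mismatches: int


@dataclass
class TECluster:
    family: str
    chrom: str
    strand: str
    anchor_starts: list[int]
    anchor_ends: list[int]

    @property
    def count(self) -> int:
        return len(self.anchor_starts)

    @property
    def start(self) -> int:
        return min(self.anchor_starts)

    @property
    def end(self) -> int:
        return max(self.anchor_ends)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def innermost(self) -> int:
        """Boundary closest to the putative insertion point."""
        return max(self.anchor_ends) if self.strand == "+" else min(self.anchor_starts)


@dataclass
class TEClusterPair:
    family: str
    chrom: str
    forward: TECluster | None
    reverse: TECluster | None
    separation: float | None
    status: str            # known | novel | ambiguous | unpaired


@dataclass
class TEInsertionCall:
    """A resolved insertion site (Table-style row).

    ``position`` is the 1-based coordinate of the T of the TA target
    dinucleotide in the reference.
    """

    family: str
    chrom: str
    position: int
    ta_confirmed: bool
    status: str            # novel | ambiguous
    left_flank: str
    right_flank: str
    support_forward: int
    support_reverse: int
    gene_feature: str | None = None

    def flank_string(self) -> str:
        if not self.ta_confirmed:
            return "Ambiguous insertion point"
        return f"{self.left_flank}[TA]{self.right_flank}"


# --------------------------------------------------------------------------
# terminus matching
# --------------------------------------------------------------------------

def _window_views(fam: TransposonFamily, window: int, read_length: int):
    """Strided (offsets x read_length) views over the four oriented
    terminal windows of a family."""
    views = []
    for terminus in ("5'", "3'"):
        wseq = fam.terminus(terminus, window)
        for oriented in (wseq, revcomp(wseq)):
            codes = encode(oriented)
            if len(codes) >= read_length:
                mat = np.lib.stride_tricks.sliding_window_view(codes, read_length)
                views.append((terminus, mat))
    return views


def _best_window_match(mate_codes: np.ndarray, views) -> tuple[str, int, int] | None:
    """(terminus, offset, mismatches) of the best match, or None."""
    best = None
    for terminus, mat in views:
        mism = (mat != mate_codes[None, :]).sum(axis=1)
        i = int(mism.argmin())
        if best is None or mism[i] < best[2]:
            best = (terminus, i, int(mism[i]))
    return best


def _known_copy_intervals(catalog: TransposonCatalog) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for fam in catalog:
        for chrom, start in fam.reference_copies:
            out.setdefault(chrom, []).append((start - 2, start + fam.length + 2))
    return out


def terminus_match(
    alignments: Iterable[PetAlignment],
    catalog: TransposonCatalog,
    window: int = 300,
    max_mismatch: int = 2,
) -> list[TerminusHit]:
    """Find pairs with a uniquely mapped anchor and a mate matching a
    terminal window of a catalog element.

    Mates that are unmapped or multi-mapped, and mates mapping within a
    known reference element copy, are searched against both strands of both
    terminal windows; a hit needs <= ``max_mismatch`` mismatches at some
    offset.
    """
    for fam in catalog:
        if window > fam.length:
            raise CatalogError(
                f"terminal window {window} exceeds {fam.name} length {fam.length}"
            )
    known = _known_copy_intervals(catalog)

    def mate_eligible(mate) -> bool:
        if mate.status != "unique":
            return True
        for s, e in known.get(mate.chrom, ()):
            if mate.pos < e and mate.pos + len(mate.seq) > s:
                return True
        return False

    fam_views = {}
    hits: list[TerminusHit] = []
    for pet in alignments:
        for anchor, mate in ((pet.r1, pet.r2), (pet.r2, pet.r1)):
            if anchor.status != "unique" or not mate.seq:
                continue
            if not mate_eligible(mate):
                continue
            rl = len(mate.seq)
            mate_codes = encode(mate.seq)
            if (mate_codes > 3).sum() > max_mismatch:
                continue
            for fam in catalog:
                key = (fam.name, rl)
                if key not in fam_views:
                    fam_views[key] = _window_views(fam, window, rl)
                best = _best_window_match(mate_codes, fam_views[key])
                if best is None or best[2] > max_mismatch:
                    continue
                terminus, offset, mism = best
                hits.append(
                    TerminusHit(
                        family=fam.name,
                        terminus=terminus,
                        chrom=anchor.chrom,
                        anchor_pos=anchor.pos,
                        anchor_strand=anchor.strand,
                        anchor_end=anchor.pos + len(anchor.seq),
                        mate_offset=offset,
                        mismatches=mism,
                    )
                )
    hits.sort(key=lambda h: (h.family, h.chrom, h.anchor_strand, h.anchor_pos))
    return hits


# --------------------------------------------------------------------------
# clustering and pairing
# --------------------------------------------------------------------------

def cluster_hits(
    hits: Sequence[TerminusHit],
    min_reads: int = 6,
    max_span: int = 220,
) -> list[TECluster]:
    """Chain same-family, same-strand anchors within ``max_span`` of each
    other; keep clusters with at least ``min_reads`` members ("more than
    five" at the default)."""
    groups: dict[tuple[str, str, str], list[TerminusHit]] = {}
    for h in hits:
        groups.setdefault((h.family, h.chrom, h.anchor_strand), []).append(h)
    clusters = []
    for (family, chrom, strand), members in groups.items():
        members = sorted(members, key=lambda h: h.anchor_pos)
        current: TECluster | None = None
        prev_pos = None
        for h in members:
            if current is not None and h.anchor_pos - prev_pos <= max_span:
                current.anchor_starts.append(h.anchor_pos)
                current.anchor_ends.append(h.anchor_end)
            else:
                if current is not None and current.count >= min_reads:
                    clusters.append(current)
                current = TECluster(family, chrom, strand, [h.anchor_pos], [h.anchor_end])
            prev_pos = h.anchor_pos
        if current is not None and current.count >= min_reads:
            clusters.append(current)
    clusters.sort(key=lambda c: (c.family, c.chrom, c.start))
    return clusters


def pair_clusters(
    clusters: Sequence[TECluster],
    catalog: TransposonCatalog,
    novel_separation: tuple[int, int] = (200, 300),
    tolerance: int = 100,
) -> list[TEClusterPair]:
    """Greedily pair forward clusters with downstream reverse clusters by
    midpoint proximity, then classify the separation.

    Separation ~ element length + 200 marks a copy present in the
    reference ("known"); separation within about 200-300 bp marks a novel
    insertion; anything else is ambiguous.  Unmatched clusters are reported
    as unpaired.
    """
    pairs: list[TEClusterPair] = []
    by_group: dict[tuple[str, str], list[TECluster]] = {}
    for c in clusters:
        by_group.setdefault((c.family, c.chrom), []).append(c)
    for (family, chrom), group in by_group.items():
        fwd = [c for c in group if c.strand == "+"]
        rev = [c for c in group if c.strand == "-"]
        candidates = []
        for i, f in enumerate(fwd):
            for j, r in enumerate(rev):
                sep = r.midpoint - f.midpoint
                if sep > 0:
                    candidates.append((sep, i, j))
        candidates.sort()
        used_f: set[int] = set()
        used_r: set[int] = set()
        elem_len = catalog[family].length
        for sep, i, j in candidates:
            if i in used_f or j in used_r:
                continue
            used_f.add(i)
            used_r.add(j)
            if abs(sep - (elem_len + 200)) <= tolerance:
                status = "known"
            elif novel_separation[0] - tolerance <= sep <= novel_separation[1] + tolerance:
                status = "novel"
            else:
                status = "ambiguous"
            pairs.append(TEClusterPair(family, chrom, fwd[i], rev[j], float(sep), status))
        for i, f in enumerate(fwd):
            if i not in used_f:
                pairs.append(TEClusterPair(family, chrom, f, None, None, "unpaired"))
        for j, r in enumerate(rev):
            if j not in used_r:
                pairs.append(TEClusterPair(family, chrom, None, r, None, "unpaired"))
    pairs.sort(key=lambda p: (p.family, p.chrom,
                              p.forward.start if p.forward else p.reverse.start))
    return pairs


# --------------------------------------------------------------------------
# insertion point resolution
# --------------------------------------------------------------------------

def _junction_support(
    t: int,
    chrom_seq: str,
    element: str,
    reads: Sequence[str],
    min_overlap: int = 3,
) -> int:
    """Reads consistent with an element inserted at TA position ``t``.

    Builds the two junction strings the insertion would create in the
    sample (left flank + TA + element start; element end + TA + right
    flank) and counts reads matching either exactly while crossing the
    junction by at least ``min_overlap`` bases.  Junction-crossing reads
    are unmapped (their element portion exceeds the mapper's mismatch
    budget), so an exact match pins the insertion point.
    """
    if not reads:
        return 0
    rl = len(reads[0])
    left = chrom_seq[max(t + 2 - rl, 0) : t + 2] + element[:rl]
    right = element[-rl:] + "TA" + chrom_seq[t + 2 : t + 2 + rl]
    boundaries = ((left, len(chrom_seq[max(t + 2 - rl, 0) : t + 2])), (right, rl))
    support = 0
    for read in reads:
        hit = False
        for oriented in (read, revcomp(read)):
            for junction, b in boundaries:
                idx = junction.find(oriented)
                while idx != -1:
                    if idx <= b - min_overlap and idx + rl >= b + min_overlap:
                        hit = True
                        break
                    idx = junction.find(oriented, idx + 1)
                if hit:
                    break
            if hit:
                break
        support += hit
    return support


def resolve_insertion_point(
    pair: TEClusterPair,
    genome: ReferenceGenome,
    margin: int = 5,
    flank: int = 10,
    catalog: TransposonCatalog | None = None,
    junction_reads: Sequence[str] | None = None,
) -> TEInsertionCall:
    """Resolve the TA insertion point of a novel cluster pair.

    A call is confirmed when a single TA dinucleotide lies within the
    innermost read boundaries +/- ``margin`` bp.  When local coverage gaps
    widen that window onto several TA candidates, the candidates are
    disambiguated by examining the reads flanking the insertion: each
    candidate predicts exact junction sequences, and only the true site
    collects junction-crossing read support (requires ``catalog`` and
    ``junction_reads``).  Remaining ties - typically TA-dense
    microsatellite contexts - give an ambiguous call.
    """
    if pair.status != "novel":
        raise TEDetectionError(f"cannot resolve a pair with status {pair.status!r}")
    seq = genome[pair.chrom]
    inner_f = pair.forward.innermost
    inner_r = pair.reverse.innermost
    lo = max(min(inner_f, inner_r) - margin, 0)
    hi = min(max(inner_f, inner_r) + margin, len(seq))

    def ta_in(a: int, b: int) -> list[int]:
        a, b = max(a, 0), min(b, len(seq))
        return [t for t in range(a, b - 1) if seq[t] == "T" and seq[t + 1] == "A"]

    candidates = ta_in(lo, hi)
    if catalog is not None and junction_reads:
        # anchor reads can overrun the junction (element start resembling
        # the reference) or leave coverage gaps, so also examine flanking
        # junction reads over a widened window: each candidate TA predicts
        # exact junction strings, and only the true site collects support
        element = catalog[pair.family].sequence
        wide = ta_in(lo - 3 * margin, hi + 3 * margin)
        support = [
            _junction_support(t, seq, element, junction_reads) for t in wide
        ]
        if support:
            best = max(support)
            if best > 0 and support.count(best) == 1:
                candidates = [wide[support.index(best)]]
    if len(candidates) == 1:
        t = candidates[0]
        return TEInsertionCall(
            family=pair.family,
            chrom=pair.chrom,
            position=t + 1,
            ta_confirmed=True,
            status="novel",
            left_flank=seq[max(t - flank, 0) : t],
            right_flank=seq[t + 2 : t + 2 + flank],
            support_forward=pair.forward.count,
            support_reverse=pair.reverse.count,
        )
    mid = (lo + hi) // 2
    return TEInsertionCall(
        family=pair.family,
        chrom=pair.chrom,
        position=mid + 1,
        ta_confirmed=False,
        status="ambiguous",
        left_flank="",
        right_flank="",
        support_forward=pair.forward.count,
        support_reverse=pair.reverse.count,
    )


def detect_te_insertions(
    alignments: Sequence[PetAlignment],
    catalog: TransposonCatalog,
    genome: ReferenceGenome,
    window: int = 300,
    max_mismatch: int = 2,
    min_reads: int = 6,
    max_span: int = 220,
    novel_separation: tuple[int, int] = (200, 300),
    tolerance: int = 100,
    margin: int = 5,
) -> tuple[list[TEInsertionCall], list[TEClusterPair]]:
    """Full detection pipeline: terminus match -> cluster -> pair -> resolve."""
    hits = terminus_match(alignments, catalog, window, max_mismatch)
    clusters = cluster_hits(hits, min_reads, max_span)
    pairs = pair_clusters(clusters, catalog, novel_separation, tolerance)
    junction_reads = collect_unmapped_reads(alignments)
    calls = [
        resolve_insertion_point(
            p, genome, margin, catalog=catalog, junction_reads=junction_reads
        )
        for p in pairs
        if p.status == "novel"
    ]
    return calls, pairs


# --------------------------------------------------------------------------
# empty-site (excision footprint) search
# --------------------------------------------------------------------------

@dataclass
class EmptySite:
    family: str
    chrom: str
    start: int             # element body interval in the reference
    end: int
    footprint: str         # "TA" or "TATA"
    support: int


def find_empty_sites(
    unmapped_reads: Sequence[str],
    catalog: TransposonCatalog,
    genome: ReferenceGenome,
    min_reads: int = 3,
    min_flank: int = 15,
) -> list[EmptySite]:
    """Search unmapped reads for excision junctions of known element copies.

    For each reference copy the candidate junction is the left flank joined
    to the right flank across a TA (or TATA) footprint; a read supports the
    junction when it matches it exactly while spanning at least
    ``min_flank`` bp on each side of the join.  Copies with at least
    ``min_reads`` supporting reads are reported as vacated (empty) sites.
    """
    if not unmapped_reads:
        return []
    rl = len(unmapped_reads[0])
    sites = []
    for fam in catalog:
        for chrom, start in fam.reference_copies:
            seq = genome[chrom]
            s, e = start, start + fam.length
            left = seq[max(s - 2 - rl, 0) : s]          # ends with the TA
            right_after_ta = seq[e + 2 : e + 2 + rl]
            right_with_ta = seq[e : e + rl]             # begins with the TA
            junctions = {
                "TA": left + right_after_ta,
                "TATA": left + right_with_ta,
            }
            boundary = len(left)
            best: tuple[int, str] | None = None
            for footprint, junction in junctions.items():
                support = set()
                for i, read in enumerate(unmapped_reads):
                    for oriented in (read, revcomp(read)):
                        idx = junction.find(oriented)
                        while idx != -1:
                            if idx <= boundary - min_flank and idx + rl >= boundary + min_flank:
                                support.add(i)
                                break
                            idx = junction.find(oriented, idx + 1)
                        if i in support:
                            break
                if len(support) >= min_reads and (best is None or len(support) > best[0]):
                    best = (len(support), footprint)
            if best is not None:
                sites.append(
                    EmptySite(fam.name, chrom, s, e, best[1], best[0])
                )
    return sites


def collect_unmapped_reads(alignments: Iterable[PetAlignment]) -> list[str]:
    out = []
    for pet in alignments:
        for half in (pet.r1, pet.r2):
            if half.status == "unmapped" and half.seq:
                out.append(half.seq)
    return out


# --------------------------------------------------------------------------
# annotation and output
# --------------------------------------------------------------------------

def annotate_te_call(
    call: TEInsertionCall, gene_models: Sequence[GeneModel]
) -> TEInsertionCall:
    """Attach the overlapping gene feature ("<gene> intron"/"<gene> exon")
    or "Intergenic"."""
    category, gene = classify_position(call.position - 1, call.chrom, gene_models)
    if gene is None:
        call.gene_feature = "Intergenic"
    elif category == "exon":
        call.gene_feature = f"{gene.gene_id} exon"
    elif category == "UTR":
        call.gene_feature = f"{gene.gene_id} UTR"
    else:
        call.gene_feature = f"{gene.gene_id} intron"
    return call


def write_te_tsv(calls: Sequence[TEInsertionCall], path) -> None:
    """Table-style TSV: Chr, Position, Type, Flanking Sequences, Gene."""
    with open(path, "w") as fh:
        fh.write("Chr\tPosition\tType\tFlanking Sequences\tGene\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.family}\t{c.flank_string()}\t"
                f"{c.gene_feature or ''}\n"
            )


def write_te_bed(calls: Sequence[TEInsertionCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            start = c.position - 1
            fh.write(
                f"{c.chrom}\t{start}\t{start + 2}\t{c.family}:{c.status}\t"
                f"{c.support_forward + c.support_reverse}\n"
            )
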