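"""Structural-variant signatures from paired-end apparent spans.

With the fragment population tightly size-selected, the apparent span of a
proper pair (its mapped outer distance on the reference) is a ruler across
the fragment.  A sample insertion removes sequence from the reference view,
so spanning pairs look *shorter* than normal; a sample deletion makes them
look *longer*; a tandem imperfect direct-repeat region yields long pairs of
*differing* sizes (a mate alignes to different repeat copies) together with
a local deficit of normally-spaced pairs.  Element-length transposon
insertions produce no spanning pairs at all and are handled by the
transposon module instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .genome import ReferenceGenome
from .mapping import PetAlignment


class AnomalyError(ValueError):
    pass


@dataclass
class FragmentStats:
    """Trimmed mean/sd of proper-pair apparent spans."""

    mean: float
    sd: float
    n: int

    def thresholds(self, k: float = 3.0, slack: float = 10.0) -> tuple[float, float]:
        lo = self.mean - k * self.sd - slack
        hi = self.mean + k * self.sd + slack
        return lo, hi


def _is_clean_proper(pet: PetAlignment) -> bool:
    return (
        pet.proper
        and pet.span is not None
        and pet.r1.status == "unique"
        and pet.r2.status == "unique"
    )


def fragment_stats(
    alignments: Sequence[PetAlignment], trim_fraction: float = 0.01
) -> FragmentStats:
    """Estimate the normal span distribution from proper unique pairs,
    trimming ``trim_fraction`` from each tail against outliers."""
    spans = np.array(
        [pet.span for pet in alignments if _is_clean_proper(pet)], dtype=float
    )
    if len(spans) < 100:
        raise AnomalyError(
            f"need >= 100 proper pairs to estimate fragment stats, got {len(spans)}"
        )
    mean = float(sps.trim_mean(spans, trim_fraction))
    limits = (trim_fraction, trim_fraction)
    sd = float(sps.mstats.trimmed_std(spans, limits=limits, ddof=1))
    return FragmentStats(mean=mean, sd=sd, n=len(spans))


@dataclass(slots=True)
class FlaggedPet:
    chrom: str
    direction: str          # "short" or "long"
    span: int
    inner_start: int        # interval between the facing read ends
    inner_end: int
    pair_id: str


def flag_anomalies(
    alignments: Sequence[PetAlignment],
    stats: FragmentStats,
    k: float = 3.0,
    slack: float = 10.0,
) -> list[FlaggedPet]:
    """Proper unique pairs whose span falls outside mean +/- k*sd (+slack)."""
    lo, hi = stats.thresholds(k, slack)
    read_length = None
    flagged = []
    for pet in alignments:
        if not _is_clean_proper(pet):
            continue
        if read_length is None:
            read_length = len(pet.r1.seq)
        if pet.span < lo:
            direction = "short"
        elif pet.span > hi:
            direction = "long"
        else:
            continue
        inner = pet.inner_interval(read_length)
        flagged.append(
            FlaggedPet(
                chrom=pet.chrom,
                direction=direction,
                span=int(pet.span),
                inner_start=inner[0],
                inner_end=inner[1],
                pair_id=pet.pair_id,
            )
        )
    flagged.sort(key=lambda f: (f.chrom, f.inner_start, f.inner_end))
    return flagged


@dataclass
class AnomalyCluster:
    chrom: str
    direction: str
    start: int              # union of member inner intervals
    end: int
    members: list[FlaggedPet] = field(default_factory=list)
    coverage_ratio: float | None = None   # local normal coverage / genome median

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def spans(self) -> np.ndarray:
        return np.array([m.span for m in self.members], dtype=float)

    @property
    def span_cv(self) -> float:
        spans = self.spans
        if spans.mean() == 0:
            return 0.0
        return float(spans.std(ddof=0) / spans.mean())


def cluster_anomalies(
    flagged: Sequence[FlaggedPet],
    max_gap: int = 50,
    min_members: int = 3,
) -> list[AnomalyCluster]:
    """Single-linkage clustering of same-direction flagged pairs whose inner
    intervals overlap or lie within ``max_gap``."""
    clusters: list[AnomalyCluster] = []
    groups: dict[tuple[str, str], list[FlaggedPet]] = {}
    for f in flagged:
        groups.setdefault((f.chrom, f.direction), []).append(f)
    for (chrom, direction), members in groups.items():
        members = sorted(members, key=lambda f: (f.inner_start, f.inner_end))
        current: AnomalyCluster | None = None
        for f in members:
            if current is not None and f.inner_start <= current.end + max_gap:
                current.members.append(f)
                current.end = max(current.end, f.inner_end)
                current.start = min(current.start, f.inner_start)
            else:
                if current is not None and current.count >= min_members:
                    clusters.append(current)
                current = AnomalyCluster(
                    chrom, direction, f.inner_start, f.inner_end, [f]
                )
        if current is not None and current.count >= min_members:
            clusters.append(current)
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def normal_pair_coverage(
    alignments: Sequence[PetAlignment],
    genome: ReferenceGenome,
    stats: FragmentStats,
    k: float = 3.0,
    slack: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per-base count of normal-span proper pairs covering each position."""
    lo, hi = stats.thresholds(k, slack)
    cover = {n: np.zeros(L + 1, dtype=np.int32) for n, L in genome.lengths.items()}
    for pet in alignments:
        if not _is_clean_proper(pet) or not (lo <= pet.span <= hi):
            continue
        start = min(pet.r1.pos, pet.r2.pos)
        track = cover[pet.chrom]
        track[start] += 1
        track[min(start + pet.span, len(track) - 1)] -= 1
    return {n: np.cumsum(track[:-1]).astype(np.int32) for n, track in cover.items()}


def attach_coverage(
    clusters: Iterable[AnomalyCluster],
    coverage: dict[str, np.ndarray],
) -> None:
    """Annotate each cluster with local normal coverage relative to the
    genome-wide median."""
    if not coverage:
        return
    median = float(np.median(np.concatenate(list(coverage.values()))))
    for cluster in clusters:
        track = coverage[cluster.chrom]
        lo = max(cluster.start, 0)
        hi = min(max(cluster.end, lo + 1), len(track))
        local = float(track[lo:hi].mean()) if hi > lo else 0.0
        cluster.coverage_ratio = local / median if median > 0 else float("nan")


@dataclass
class SVCall:
    type: str               # insertion | deletion | direct_repeat | unclassified_long
    chrom: str
    start: int              # 0-based inner interval
    end: int
    size: float | None      # bp estimate; None for direct_repeat
    support: int

    def to_bed_line(self) -> str:
        size = "NA" if self.size is None else f"{self.size:.0f}"
        return (
            f"{self.chrom}\t{self.start}\t{self.end}\t{self.type}\t{self.support}"
            f"\t.\t{self.start}\t{self.end}\t0,0,0\tSIZE={size}\n"
        )


def call_sv(
    cluster: AnomalyCluster,
    stats: FragmentStats,
    cv_threshold: float = 0.1,
    coverage_threshold: float = 0.25,
) -> SVCall:
    """Classify one anomaly cluster.

    Short clusters are insertions (size = normal mean - member span mean);
    long clusters with coherent spans are deletions (member span mean -
    normal mean); long clusters with dispersed spans over a region lacking
    normal coverage carry the direct-repeat signature; remaining long
    clusters are left unclassified.
    """
    mean_span = float(cluster.spans.mean())
    if cluster.direction == "short":
        return SVCall(
            "insertion", cluster.chrom, cluster.start, cluster.end,
            stats.mean - mean_span, cluster.count,
        )
    if cluster.span_cv <= cv_threshold:
        return SVCall(
            "deletion", cluster.chrom, cluster.start, cluster.end,
            mean_span - stats.mean, cluster.count,
        )
    if (
        cluster.coverage_ratio is not None
        and cluster.coverage_ratio < coverage_threshold
    ):
        return SVCall(
            "direct_repeat", cluster.chrom, cluster.start, cluster.end,
            None, cluster.count,
        )
    return SVCall(
        "unclassified_long", cluster.chrom, cluster.start, cluster.end,
        None, cluster.count,
    )


def detect_svs(
    alignments: Sequence[PetAlignment],
    genome: ReferenceGenome,
    k: float = 3.0,
    slack: float = 10.0,
    max_gap: int = 50,
    min_members: int = 3,
    cv_threshold: float = 0.1,
    coverage_threshold: float = 0.25,
    trim_fraction: float = 0.01,
    stats: FragmentStats | None = None,
) -> tuple[list[SVCall], FragmentStats]:
    """Full anomaly pipeline: stats -> flag -> cluster -> classify."""
    if stats is None:
        stats = fragment_stats(alignments, trim_fraction)
    flagged = flag_anomalies(alignments, stats, k, slack)
    clusters = cluster_anomalies(flagged, max_gap, min_members)
    coverage = normal_pair_coverage(alignments, genome, stats, k, slack)
    attach_coverage(clusters, coverage)
    calls = [
        call_sv(c, stats, cv_threshold, coverage_threshold) for c in clusters
    ]
    return calls, stats


def write_sv_bed(calls: Sequence[SVCall], path) -> None:
    with open(path, "w") as fh:
        for call in calls:
            fh.write(call.to_bed_line())


def write_sv_tsv(calls: Sequence[SVCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("type\tchrom\tstart\tend\tsize_bp\tsupport\n")
        for c in calls:
            size = "NA" if c.size is None else f"{c.size:.1f}"
            fh.write(f"{c.type}\t{c.chrom}\t{c.start + 1}\t{c.end}\t{size}\t{c.support}\n")
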