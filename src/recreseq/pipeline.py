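"""End-to-end orchestration: simulate -> map -> call -> report.

Every stage is deterministic given the config seed; the run manifest
records the config snapshot and SHA-256 digests of all outputs so a rerun
can be verified byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anomaly import SVCall, detect_svs, write_sv_bed, write_sv_tsv
from .catalog import TransposonCatalog
from .genes import random_gene_models, write_gff3, annotate_call
from .genome import ReferenceGenome
from .mapping import GenomeIndex, map_read_pairs, write_sam
from .simulate import (
    SimConfig,
    SimulationTruth,
    derive_sample_genome,
    generate_reference,
    simulate_pets,
    write_fastq,
)
from .spectrum import (
    VariantCall,
    build_spectrum,
    pileup_consensus,
    run_summary,
    write_vcf,
)
from .transposons import (
    TEInsertionCall,
    annotate_te_call,
    collect_unmapped_reads,
    detect_te_insertions,
    find_empty_sites,
    write_te_bed,
    write_te_tsv,
)

logger = logging.getLogger("recreseq")


@dataclass
class PipelineConfig:
    """Simulation settings plus the tunables of every calling stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed_length: int = 14
    max_mismatches: int = 2
    min_depth: int = 4
    min_fraction: float = 0.8
    sv_k: float = 3.0
    sv_slack: float = 10.0
    sv_max_gap: int = 50
    sv_min_members: int = 3
    sv_cv_threshold: float = 0.1
    sv_coverage_threshold: float = 0.25
    te_window: int = 300
    te_max_mismatch: int = 2
    te_min_reads: int = 6
    te_tolerance: int = 100
    n_genes: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        sim = data.pop("sim")
        sim["fragment_range"] = list(sim["fragment_range"])
        with open(path, "w") as fh:
            yaml.safe_dump({"simulate": sim, **data}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(data.pop("simulate", {}))
        return cls(sim=sim, **data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages and write the full artifact set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim

    needs_catalog = bool(
        sim.te_insertions or sim.te_reference_copies or sim.te_excisions
    )
    catalog = TransposonCatalog.synthetic(seed=sim.seed) if needs_catalog else None

    logger.info("stage simulate: generating reference (%d bp)",
                sum(sim.chromosome_lengths.values()))
    ref = generate_reference(sim, catalog)
    sample, truth = derive_sample_genome(ref, sim, catalog)
    reads, truth = simulate_pets(sample, sim, truth)
    logger.info("stage simulate: %d events planted, %d read pairs",
                len(truth.substitutions) + len(truth.te_insertions)
                + len(truth.deletions) + len(truth.small_insertions)
                + len(truth.repeat_contractions) + len(truth.te_excisions),
                len(reads))

    ref.to_fasta(outdir / "reference.fa")
    sample.to_fasta(outdir / "sample.fa")
    write_fastq(reads, outdir / "reads_1.fq", outdir / "reads_2.fq")
    truth.to_tsv(outdir / "truth.tsv")
    truth.to_vcf(ref, outdir / "truth.vcf")
    truth.to_bed(outdir / "truth.bed")
    if catalog is not None:
        catalog.write(outdir / "catalog")

    gene_models = []
    if config.n_genes:
        gene_models = random_gene_models(ref, config.n_genes, rng=sim.seed)
        write_gff3(gene_models, outdir / "genes.gff3")

    logger.info("stage map: indexing (k=%d) and mapping %d pairs",
                config.seed_length, len(reads))
    index = GenomeIndex(ref, k=config.seed_length)
    expected = sum(sim.fragment_range) / 2
    alignments = map_read_pairs(
        reads, index, config.max_mismatches, expected_span=expected
    )
    write_sam(alignments, ref, outdir / "alignments.sam")

    total = 2 * len(alignments)
    aligned = sum(
        (pet.r1.status != "unmapped") + (pet.r2.status != "unmapped")
        for pet in alignments
    )
    summary = run_summary(total, aligned, sim.read_length, ref.total_size)
    with open(outdir / "run_summary.tsv", "w") as fh:
        fh.write("total_reads\taligned_reads\tpercent_aligned\tfold_coverage\n")
        fh.write(f"{total}\t{aligned}\t{summary.percent_aligned}\t{summary.fold_coverage}\n")
    logger.info("stage map: %d/%d reads aligned (%d%%), ~%dx coverage",
                aligned, total, summary.percent_aligned, summary.fold_coverage)

    logger.info("stage call-snv: pileup consensus")
    snv_calls = pileup_consensus(
        alignments, ref, config.min_depth, config.min_fraction
    )
    for call in snv_calls:
        annotate_call(call, gene_models, ref)
    write_vcf(snv_calls, ref, outdir / "calls.vcf")
    build_spectrum(snv_calls, ref).to_tsv(outdir / "spectrum.tsv")
    logger.info("stage call-snv: %d substitutions called", len(snv_calls))

    logger.info("stage call-sv: insert-size anomalies")
    sv_calls, _stats = detect_svs(
        alignments,
        ref,
        k=config.sv_k,
        slack=config.sv_slack,
        max_gap=config.sv_max_gap,
        min_members=config.sv_min_members,
        cv_threshold=config.sv_cv_threshold,
        coverage_threshold=config.sv_coverage_threshold,
    )
    write_sv_bed(sv_calls, outdir / "sv.bed")
    write_sv_tsv(sv_calls, outdir / "sv.tsv")
    logger.info("stage call-sv: %d calls", len(sv_calls))

    te_calls: list[TEInsertionCall] = []
    if catalog is not None:
        logger.info("stage call-te: terminus matching")
        te_calls, _pairs = detect_te_insertions(
            alignments,
            catalog,
            ref,
            window=config.te_window,
            max_mismatch=config.te_max_mismatch,
            min_reads=config.te_min_reads,
            max_span=max(sim.fragment_range),
            tolerance=config.te_tolerance,
        )
        for call in te_calls:
            annotate_te_call(call, gene_models)
        empty = find_empty_sites(
            collect_unmapped_reads(alignments), catalog, ref
        )
        with open(outdir / "empty_sites.tsv", "w") as fh:
            fh.write("family\tchrom\tstart\tend\tfootprint\tsupport\n")
            for site in empty:
                fh.write(
                    f"{site.family}\t{site.chrom}\t{site.start + 1}\t{site.end}"
                    f"\t{site.footprint}\t{site.support}\n"
                )
        logger.info("stage call-te: %d insertion calls, %d empty sites",
                    len(te_calls), len(empty))
    write_te_tsv(te_calls, outdir / "te_calls.tsv")
    write_te_bed(te_calls, outdir / "te_calls.bed")

    report = recovery_report(truth, snv_calls, sv_calls, te_calls)
    report.to_csv(outdir / "recovery.tsv", sep="\t")

    config.to_yaml(outdir / "config.yaml")
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": sim.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "digests": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


# --------------------------------------------------------------------------
# recovery report
# --------------------------------------------------------------------------

def _interval_close(a: tuple[int, int], b: tuple[int, int], window: int) -> bool:
    return a[0] <= b[1] + window and b[0] <= a[1] + window


def recovery_report(
    truth: SimulationTruth,
    snv_calls: list[VariantCall] | None = None,
    sv_calls: list[SVCall] | None = None,
    te_calls: list[TEInsertionCall] | None = None,
    window: int = 10,
) -> pd.DataFrame:
    """Per-event-class sensitivity and false-positive counts against truth.

    An event is recovered when a call of the right class lies within
    ``window`` bp (substitutions must match exactly); calls matching no
    truth event count as false positives.
    """
    snv_calls = snv_calls or []
    sv_calls = sv_calls or []
    te_calls = te_calls or []
    rows = {}

    truth_subs = {(s.chrom, s.pos, s.ref, s.alt) for s in truth.substitutions}
    called_subs = {(c.chrom, c.pos - 1, c.ref, c.alt) for c in snv_calls}
    rows["substitution"] = {
        "n_truth": len(truth_subs),
        "n_called": len(called_subs),
        "recovered": len(truth_subs & called_subs),
        "false_positives": len(called_subs - truth_subs),
        "mean_position_error": 0.0 if truth_subs & called_subs else float("nan"),
    }

    te_by_family = [(t.chrom, t.ta_pos, t.family) for t in truth.te_insertions]
    matched = set()
    errors = []
    fp = 0
    for call in te_calls:
        hit = None
        for i, (chrom, ta_pos, family) in enumerate(te_by_family):
            if (
                i not in matched
                and call.family == family
                and call.chrom == chrom
                and abs((call.position - 1) - ta_pos) <= window
            ):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            matched.add(hit)
            errors.append(abs((call.position - 1) - te_by_family[hit][1]))
    rows["te_insertion"] = {
        "n_truth": len(te_by_family),
        "n_called": len(te_calls),
        "recovered": len(matched),
        "false_positives": fp,
        "mean_position_error": float(pd.Series(errors).mean()) if errors else float("nan"),
    }

    def sv_class_row(truth_intervals, call_type):
        calls = [c for c in sv_calls if c.type == call_type]
        matched = set()
        fp = 0
        for c in calls:
            hit = None
            for i, (chrom, iv) in enumerate(truth_intervals):
                if i not in matched and c.chrom == chrom and _interval_close(
                    (c.start, c.end), iv, window
                ):
                    hit = i
                    break
            if hit is None:
                fp += 1
            else:
                matched.add(hit)
        return {
            "n_truth": len(truth_intervals),
            "n_called": len(calls),
            "recovered": len(matched),
            "false_positives": fp,
            "mean_position_error": float("nan"),
        }

    rows["deletion"] = sv_class_row(
        [(d.chrom, (d.start, d.start + d.length)) for d in truth.deletions],
        "deletion",
    )
    rows["insertion"] = sv_class_row(
        [(i.chrom, (i.start, i.start + 1)) for i in truth.small_insertions],
        "insertion",
    )
    rows["direct_repeat"] = sv_class_row(
        [
            (r.chrom, (r.start, r.start + r.unit_length * r.ref_copies))
            for r in truth.repeat_contractions
        ],
        "direct_repeat",
    )

    report = pd.DataFrame(rows).T
    report["sensitivity"] = report.apply(
        lambda r: r.recovered / r.n_truth if r.n_truth else float("nan"), axis=1
    )
    report.index.name = "event_class"
    return report
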