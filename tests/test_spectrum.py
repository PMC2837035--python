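"""Substitution classification, spectrum tables, Ts/Tv, densities, pileup
calling and run summaries."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recreseq import (
    SPECTRUM_CLASSES,
    SpectrumTable,
    build_spectrum,
    classify_substitution,
    pileup_consensus,
    regional_density,
    run_summary,
    ts_tv_ratio,
)
from recreseq.genome import revcomp
from recreseq.spectrum import VariantCall, format_ratio, write_vcf

from conftest import make_half, make_pet, random_genome
from recreseq.mapping import PetAlignment

# The published per-chromosome count matrix used as a worked example
# (columns I, II, III, IV, V, X).
COUNTS = pd.DataFrame(
    {
        "I": [55, 10, 9, 6, 5, 5],
        "II": [11, 16, 7, 6, 8, 3],
        "III": [14, 17, 12, 6, 5, 6],
        "IV": [16, 17, 14, 9, 4, 7],
        "V": [14, 18, 17, 12, 7, 12],
        "X": [31, 12, 18, 17, 10, 5],
    },
    index=list(SPECTRUM_CLASSES),
)


ALL_CHANGES = [
    ("G", "A", "G:C to A:T"),
    ("C", "T", "G:C to A:T"),
    ("A", "T", "A:T to T:A"),
    ("T", "A", "A:T to T:A"),
    ("G", "T", "G:C to T:A"),
    ("C", "A", "G:C to T:A"),
    ("A", "G", "A:T to G:C"),
    ("T", "C", "A:T to G:C"),
    ("A", "C", "A:T to C:G"),
    ("T", "G", "A:T to C:G"),
    ("G", "C", "G:C to C:G"),
    ("C", "G", "G:C to C:G"),
]


@pytest.mark.parametrize("ref,alt,label", ALL_CHANGES)
def test_all_twelve_changes_classified(ref, alt, label):
    assert classify_substitution(ref, alt) == label


@given(
    st.sampled_from("ACGT"), st.sampled_from("ACGT")
)
@settings(derandomize=True, max_examples=40)
def test_classification_complement_symmetry(ref, alt):
    if ref == alt:
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)
    else:
        assert classify_substitution(ref, alt) == classify_substitution(
            revcomp(ref), revcomp(alt)
        )


class TestTsTv:
    def test_uniform_counts_give_half(self):
        counts = {c: 7 for c in SPECTRUM_CLASSES}
        assert ts_tv_ratio(counts) == pytest.approx(0.5)

    def test_zero_transversions_undefined(self):
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        counts["G:C to A:T"] = 10
        assert math.isnan(ts_tv_ratio(counts))

    def test_formatting_matches_table_convention(self):
        assert format_ratio(61 / 29) == "2.1"
        assert format_ratio(17 / 34) == "0.5"
        assert format_ratio(26 / 54) == "0.48"
        assert format_ratio(48 / 45) == "1.07"
        assert format_ratio(197 / 244) == "0.81"
        assert format_ratio(float("nan")) == "NA"


class TestSpectrumTable:
    def test_published_matrix_totals(self):
        table = SpectrumTable(COUNTS)
        assert table.grand_total == 441
        assert table.class_totals()["G:C to A:T"] == 141
        assert table.chromosome_totals()["I"] == 90
        # chromosome I alone carries as many G:C to A:T as II-V combined
        assert COUNTS.loc["G:C to A:T", ["II", "III", "IV", "V"]].sum() == 55

    def test_row_and_column_sums_conserved(self):
        table = SpectrumTable(COUNTS)
        assert table.class_totals().sum() == table.grand_total
        assert table.chromosome_totals().sum() == table.grand_total

    def test_ts_tv_row_formats_as_published(self):
        table = SpectrumTable(COUNTS)
        row = table.to_frame().loc["Ts/Tv"]
        assert list(row) == ["2.1", "0.5", "0.5", "0.6", "0.48", "1.07", "0.81"]

    def test_empty_call_set(self):
        table = build_spectrum([], ["I", "II"])
        assert table.grand_total == 0
        assert math.isnan(table.ts_tv())

    def test_tsv_layout(self, tmp_path):
        table = SpectrumTable(COUNTS)
        path = tmp_path / "spectrum.tsv"
        table.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        assert float(back.loc["Total", "Total"]) == 441
        assert back.loc["Ts/Tv", "I"] == "2.1"


def _pileup_fixture(depths: dict[int, tuple[int, int]]):
    """Build alignments over a toy genome giving (ref_count, alt_count)
    pileups at chosen sites."""
    genome = random_genome(2_000, seed=31)
    seq = genome["chrI"]
    alignments = []
    pid = 0
    for pos, (n_ref, n_alt) in depths.items():
        site = pos + 20
        ref_base = seq[site]
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        for i in range(n_ref + n_alt):
            read = seq[pos : pos + 42]
            if i >= n_ref:
                read = read[:20] + alt_base + read[21:]
            half = make_half("chrI", pos, "+", read)
            mate = make_half(None, -1, ".", "A" * 42, status="unmapped")
            alignments.append(PetAlignment(f"p{pid}", half, mate, False, None))
            pid += 1
    return genome, alignments


class TestPileupConsensus:
    def test_full_depth_alt_site_called(self):
        genome, alignments = _pileup_fixture({100: (0, 21)})
        calls = pileup_consensus(alignments, genome)
        assert len(calls) == 1
        call = calls[0]
        assert call.pos == 121 and call.alt_depth == 21 and call.depth == 21

    def test_depth_below_minimum_not_called(self):
        genome, alignments = _pileup_fixture({100: (0, 3)})
        assert pileup_consensus(alignments, genome) == []

    def test_low_fraction_not_called(self):
        genome, alignments = _pileup_fixture({100: (10, 11)})  # 0.52 alt
        assert pileup_consensus(alignments, genome) == []

    def test_multi_mapped_reads_excluded(self):
        genome, alignments = _pileup_fixture({100: (0, 21)})
        for pet in alignments:
            pet.r1.status = "multi"
        assert pileup_consensus(alignments, genome) == []

    def test_planted_spectrum_recovered_exactly(self, mixed_sim):
        """At 21x error-free coverage the called spectrum equals the
        planted spectrum."""
        calls = pileup_consensus(mixed_sim.alignments, mixed_sim.ref)
        called = {(c.chrom, c.pos - 1, c.ref, c.alt) for c in calls}
        planted = {
            (s.chrom, s.pos, s.ref, s.alt) for s in mixed_sim.truth.substitutions
        }
        assert planted <= called
        extras = called - planted
        # edge artifacts may appear only at structural-event junctions
        for chrom, pos, _r, _a in extras:
            near_structural = any(
                abs(pos - d.start) < 300 or abs(pos - (d.start + d.length)) < 300
                for d in mixed_sim.truth.deletions
            ) or any(
                abs(pos - i.start) < 300 for i in mixed_sim.truth.small_insertions
            ) or any(
                abs(pos - t.ta_pos) < 300 for t in mixed_sim.truth.te_insertions
            ) or any(
                r.start - 300 < pos < r.start + r.unit_length * r.ref_copies + 300
                for r in mixed_sim.truth.repeat_contractions
            )
            assert near_structural, (chrom, pos)


class TestRegionalDensity:
    def _calls(self, n, chrom="I", start=0):
        return [
            VariantCall(chrom, start + 10 * i + 1, "G", "A", 20, 21, "G:C to A:T")
            for i in range(n)
        ]

    def test_published_cluster_density(self):
        region_map = pd.DataFrame(
            {"chrom": ["I"], "start": [0], "end": [24_000_000], "label": ["cluster"]}
        )
        out = regional_density(self._calls(97), region_map)
        assert round(out.loc["cluster", "per_mbp"], 2) == 4.04

    def test_arm_density_by_division(self):
        region_map = pd.DataFrame(
            {"chrom": ["I"], "start": [0], "end": [60_000_000], "label": ["arm"]}
        )
        out = regional_density(self._calls(251), region_map)
        assert round(out.loc["arm", "per_mbp"], 2) == 4.18

    def test_zero_calls_zero_density(self):
        region_map = pd.DataFrame(
            {"chrom": ["I"], "start": [0], "end": [1_000_000], "label": ["arm"]}
        )
        out = regional_density([], region_map)
        assert out.loc["arm", "count"] == 0
        assert out.loc["arm", "per_mbp"] == 0.0

    def test_zero_span_label_rejected(self):
        region_map = pd.DataFrame(
            {"chrom": ["I"], "start": [5], "end": [5], "label": ["arm"]}
        )
        with pytest.raises(ValueError):
            regional_density([], region_map)

    def test_overlapping_intervals_rejected(self):
        region_map = pd.DataFrame(
            {
                "chrom": ["I", "I"],
                "start": [0, 50],
                "end": [100, 150],
                "label": ["arm", "cluster"],
            }
        )
        with pytest.raises(ValueError):
            regional_density([], region_map)


class TestRunSummary:
    def test_published_numbers(self):
        s = run_summary(60_601_198, 50_595_466, 42, 100_270_000)
        assert s.percent_aligned == 83
        assert s.fold_coverage == 21

    def test_all_aligned(self):
        assert run_summary(100, 100, 42, 10_000).percent_aligned == 100

    def test_none_aligned(self):
        s = run_summary(100, 0, 42, 10_000)
        assert s.percent_aligned == 0 and s.fold_coverage == 0

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            run_summary(10, 5, 42, 0)

    def test_aligned_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            run_summary(10, 11, 42, 1000)


def test_uniform_random_substitutions_approach_half():
    """With all 12 strand-specific changes equiprobable, Ts/Tv tends to
    2 transitions / 4 transversions = 0.5."""
    rng = np.random.default_rng(123)
    refs = rng.integers(0, 4, size=100_000)
    alts = (refs + rng.integers(1, 4, size=100_000)) % 4
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    for r, a in zip(refs, alts):
        counts[classify_substitution("ACGT"[r], "ACGT"[a])] += 1
    assert abs(ts_tv_ratio(counts) - 0.5) <= 0.02


def test_vcf_emission_is_parseable(tmp_path, mixed_sim):
    calls = pileup_consensus(mixed_sim.alignments, mixed_sim.ref)
    path = tmp_path / "calls.vcf"
    write_vcf(calls, mixed_sim.ref, path)
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert len(records) == len(calls)
    assert records[0].info["DP"] == calls[0].depth
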