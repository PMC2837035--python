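"""Pigeonhole mapper: index semantics, exactness against brute force, pair
resolution and SAM round trips."""
from __future__ import annotations

import numpy as np
import pysam
import pytest

from recreseq import (
    GenomeIndex,
    ReferenceGenome,
    map_pair,
    map_read_pairs,
    map_single,
    read_sam,
    write_sam,
)
from recreseq.genome import encode, revcomp
from recreseq.mapping import MappingError

from conftest import random_genome


def brute_force_hits(read: str, genome: ReferenceGenome, max_mm: int) -> set:
    """Independent all-positions Hamming scan over both strands."""
    hits = set()
    rl = len(read)
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < rl:
            continue
        g = encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(g, rl)
        for strand, q in (("+", encode(read)), ("-", encode(revcomp(read)))):
            mism = (windows != q).sum(axis=1)
            for p in np.nonzero(mism <= max_mm)[0]:
                hits.add((chrom, int(p), strand, int(mism[p])))
    return hits


@pytest.fixture(scope="module")
def genome():
    return random_genome(50_000, seed=123)


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome, k=14)


class TestIndex:
    def test_every_kmer_retrievable(self, genome, index):
        seq = genome["chrI"]
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, len(seq) - 14, size=50):
            kmer = seq[pos : pos + 14]
            assert (("chrI", int(pos), "+") in index.positions(kmer))

    def test_palindromic_kmer_reports_both_strands(self):
        half = "ACGTAGA"
        pal = half + revcomp(half)  # 14-mer, self-reverse-complementary
        assert revcomp(pal) == pal
        flank = "GGGG" * 5
        genome = ReferenceGenome({"c": flank + pal + flank})
        index = GenomeIndex(genome, k=14)
        hits = index.positions(pal)
        strands = {s for _, _, s in hits}
        assert strands == {"+", "-"}
        assert len([h for h in hits if h[1] == 20]) == 2

    def test_k_longer_than_chromosome_gives_empty_index(self):
        genome = ReferenceGenome({"c": "ACGTACGTACG"})  # 11 bp < k
        index = GenomeIndex(genome, k=14)
        assert len(index.sorted_kmers) == 0

    def test_seed_length_bounds(self, genome):
        with pytest.raises(MappingError):
            GenomeIndex(genome, k=4)


class TestMapSingle:
    def test_error_free_read_maps_uniquely_to_origin(self, genome, index):
        read = genome["chrI"][10_000:10_042]
        result = map_single(read, index, 2)
        assert result.status == "unique"
        assert result.best == ("chrI", 10_000, "+", 0)

    def test_reverse_strand_read(self, genome, index):
        read = revcomp(genome["chrI"][5_000:5_042])
        result = map_single(read, index, 2)
        assert result.status == "unique"
        assert result.best.pos == 5_000 and result.best.strand == "-"

    def test_three_errors_unmapped_at_budget_two(self, genome, index):
        read = list(genome["chrI"][20_000:20_042])
        for i, sub in ((3, "A"), (18, "C"), (33, "G")):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        result = map_single("".join(read), index, 2)
        assert result.status == "unmapped"

    def test_two_copy_repeat_gives_multi_with_two_loci(self):
        rng = np.random.default_rng(5)
        unique = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2_000))
        copy = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        genome = ReferenceGenome({"c": unique + copy + unique[::-1] + copy + unique})
        index = GenomeIndex(genome, k=14)
        read = copy[20:62]
        result = map_single(read, index, 2)
        assert result.status == "multi"
        best = [a for a in result.alignments if a.mismatches == 0]
        assert len(best) == 2
        assert brute_force_hits(read, genome, 2) == {
            (a.chrom, a.pos, a.strand, a.mismatches) for a in result.alignments
        }

    def test_read_with_n_bases_counts_mismatches(self, genome, index):
        read = genome["chrI"][30_000:30_042]
        read = read[:10] + "NN" + read[12:]
        result = map_single(read, index, 2)
        assert result.status == "unique"
        assert result.best.mismatches == 2

    def test_read_too_short_for_seed_partition(self, index):
        with pytest.raises(MappingError):
            map_single("ACGTACGTACGTACGTACGT", index, 2)  # 20 < 3*14

    def test_agrees_with_brute_force_on_random_mutated_reads(self, genome, index):
        rng = np.random.default_rng(7)
        seq = genome["chrI"]
        for _ in range(60):
            pos = int(rng.integers(0, len(seq) - 42))
            read = list(seq[pos : pos + 42])
            for i in rng.choice(42, size=int(rng.integers(0, 3)), replace=False):
                read[i] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            if rng.integers(2):
                read = revcomp(read)
            got = {
                (a.chrom, a.pos, a.strand, a.mismatches)
                for a in map_single(read, index, 2).alignments
            }
            assert got == brute_force_hits(read, genome, 2)


class TestMapPair:
    def test_error_free_pair_has_expected_span(self, genome, index):
        seq = genome["chrI"]
        frag = seq[8_000:8_200]
        pet = map_pair(frag[:42], revcomp(frag[-42:]), index, 2)
        assert pet.proper and pet.span == 200
        assert pet.r1.pos == 8_000 and pet.r2.pos == 8_158
        assert pet.r1.strand == "+" and pet.r2.strand == "-"

    def test_one_end_mapped_retains_mate_sequence(self, genome, index):
        seq = genome["chrI"]
        foreign = "ACGT" * 10 + "AC"
        pet = map_pair(seq[1000:1042], foreign, index, 2)
        if pet.r2.status == "unmapped":
            assert pet.r2.seq == foreign
            assert pet.r1.status == "unique"
            assert not pet.proper and pet.span is None

    def test_mates_on_different_chromosomes_not_proper(self):
        g1 = random_genome(20_000, seed=1)["chrI"]
        g2 = random_genome(20_000, seed=2)["chrI"]
        genome = ReferenceGenome({"chrI": g1, "chrII": g2})
        index = GenomeIndex(genome, k=14)
        pet = map_pair(g1[500:542], revcomp(g2[700:742]), index, 2)
        assert not pet.proper and pet.span is None
        assert pet.r1.chrom == "chrI" and pet.r2.chrom == "chrII"

    def test_completeness_on_clean_simulation(self, clean_sim):
        """Error-free reads from unique sequence all map uniquely to their
        true origins with exact spans."""
        origins = clean_sim.truth.read_origins
        rl = clean_sim.config.read_length
        for i, pet in enumerate(clean_sim.alignments):
            s = int(origins.starts[i])
            F = int(origins.frag_lengths[i])
            left, right = (pet.r1, pet.r2) if origins.strands[i] == 0 else (pet.r2, pet.r1)
            assert left.status == "unique" and right.status == "unique"
            assert left.pos == s and left.strand == "+"
            assert right.pos == s + F - rl and right.strand == "-"
            assert pet.proper and pet.span == F


class TestSamIO:
    def test_round_trip_preserves_fields(self, tmp_path, clean_sim):
        subset = clean_sim.alignments[:100]
        path = tmp_path / "out.sam"
        write_sam(subset, clean_sim.ref, path)
        loaded = read_sam(path)
        assert len(loaded) == 100
        for orig, back in zip(subset, loaded):
            assert back.pair_id == orig.pair_id
            assert back.proper == orig.proper and back.span == orig.span
            for a, b in ((orig.r1, back.r1), (orig.r2, back.r2)):
                assert (a.status, a.chrom, a.pos, a.strand, a.seq) == (
                    b.status, b.chrom, b.pos, b.strand, b.seq
                )
                if a.status != "unmapped":
                    assert a.mismatches == b.mismatches

    def test_empty_alignment_set_gives_header_only_sam(self, tmp_path, clean_sim):
        path = tmp_path / "empty.sam"
        write_sam([], clean_sim.ref, path)
        text = path.read_text()
        assert all(line.startswith("@") for line in text.splitlines())
        assert read_sam(path) == []

    def test_proper_pair_flags_and_tlen_signs(self, tmp_path, clean_sim):
        proper = [p for p in clean_sim.alignments if p.proper][:5]
        path = tmp_path / "flags.sam"
        write_sam(proper, clean_sim.ref, path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            by_name: dict[str, list] = {}
            for seg in fh:
                assert seg.flag & 0x1 and seg.flag & 0x2
                by_name.setdefault(seg.query_name, []).append(seg)
        for segs in by_name.values():
            tlens = sorted(seg.template_length for seg in segs)
            assert tlens[0] == -tlens[1] != 0

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrI\tLN:100\n"
            "r1\t0\tchrI\t90\t60\t42M\t*\t0\t0\t" + "A" * 42 + "\t" + "I" * 42 + "\n"
        )
        with pytest.raises(MappingError, match="r1"):
            read_sam(path)


def test_multi_mapped_pair_rescued_by_expected_span():
    """A mate inside a two-copy repeat is placed at the copy that restores a
    normal span when that choice is unambiguous."""
    rng = np.random.default_rng(11)
    u = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3_000))
    copy = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
    genome = ReferenceGenome({"c": u[:1000] + copy + u[1000:2000] + copy + u[2000:]})
    index = GenomeIndex(genome, k=14)
    seq = genome["c"]
    r1 = seq[880:922]            # unique, upstream of the first copy
    r2 = revcomp(seq[1020:1062]) # fully inside the first copy: multi
    pet = map_pair(r1, r2, index, 2, expected_span=200.0)
    assert pet.r1.status == "unique"
    assert pet.r2.status == "multi"
    assert pet.proper and pet.span == 182
    assert pet.r2.pos == 1020
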