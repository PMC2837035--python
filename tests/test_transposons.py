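"""Transposon insertion detection: terminus matching, cluster thresholds,
separation-based classification, TA resolution, empty sites, annotation."""
from __future__ import annotations

import numpy as np
import pytest

from recreseq import (
    SimConfig,
    TransposonCatalog,
    cluster_hits,
    detect_te_insertions,
    find_empty_sites,
    pair_clusters,
    resolve_insertion_point,
    terminus_match,
)
from recreseq.catalog import CatalogError
from recreseq.genes import GeneModel
from recreseq.genome import revcomp
from recreseq.mapping import PetAlignment
from recreseq.transposons import (
    TECluster,
    TEClusterPair,
    TEDetectionError,
    TerminusHit,
    annotate_te_call,
    collect_unmapped_reads,
)

from conftest import make_bundle, make_half


@pytest.fixture(scope="module")
def catalog():
    return TransposonCatalog.synthetic(seed=1)


def _pair_with_mate(catalog, mate_seq, chrom="chrI", anchor_pos=5_000):
    anchor = make_half(chrom, anchor_pos, "+", "A" * 42)
    mate = make_half(None, -1, ".", mate_seq, status="unmapped")
    return PetAlignment("p0", anchor, mate, False, None)


class TestTerminusMatch:
    def test_exact_five_prime_prefix_hits(self, catalog):
        mate = catalog["Tc1"].sequence[:42]
        hits = terminus_match([_pair_with_mate(catalog, mate)], catalog)
        assert any(h.family == "Tc1" and h.terminus == "5'" for h in hits)

    def test_reverse_complement_terminus_hits(self, catalog):
        mate = revcomp(catalog["Tc2"].sequence[-42:])
        hits = terminus_match([_pair_with_mate(catalog, mate)], catalog)
        assert any(h.family == "Tc2" and h.terminus == "3'" for h in hits)

    def test_element_midpoint_outside_windows_no_hit(self, catalog):
        mate = catalog["Tc1"].sequence[700:742]
        assert terminus_match([_pair_with_mate(catalog, mate)], catalog) == []

    def test_mismatch_budget(self, catalog):
        mate = list(catalog["Tc1"].sequence[:42])
        for i in (5, 15, 25):
            mate[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[i]]
        hits = terminus_match([_pair_with_mate(catalog, "".join(mate))], catalog)
        assert hits == []  # 3 mismatches > budget of 2

    def test_window_longer_than_element_rejected(self, catalog):
        with pytest.raises(CatalogError):
            terminus_match([], catalog, window=3_000)

    def test_uniquely_mapped_mate_outside_copies_ignored(self, catalog):
        anchor = make_half("chrI", 5_000, "+", "A" * 42)
        mate = make_half("chrI", 5_200, "-", catalog["Tc1"].sequence[:42])
        pet = PetAlignment("p0", anchor, mate, True, 242)
        assert terminus_match([pet], catalog) == []


def _hits(family, strand, positions, chrom="chrI"):
    return [
        TerminusHit(family, "5'", chrom, p, strand, p + 42, 0, 0) for p in positions
    ]


class TestClusterHits:
    def test_six_hits_within_span_retained(self):
        clusters = cluster_hits(_hits("Tc1", "+", [100, 120, 140, 160, 200, 250]))
        assert len(clusters) == 1 and clusters[0].count == 6

    def test_five_hits_discarded(self):
        assert cluster_hits(_hits("Tc1", "+", [100, 120, 140, 160, 200])) == []

    def test_distant_groups_split(self):
        positions = [100, 110, 120, 130, 140, 150] + [5100, 5110, 5120, 5130, 5140, 5150]
        clusters = cluster_hits(_hits("Tc1", "+", positions))
        assert len(clusters) == 2

    def test_strands_kept_separate(self):
        hits = _hits("Tc1", "+", [100, 110, 120]) + _hits("Tc1", "-", [130, 140, 150])
        assert cluster_hits(hits, min_reads=3) != cluster_hits(hits[:3], min_reads=3)
        clusters = cluster_hits(hits, min_reads=3)
        assert {c.strand for c in clusters} == {"+", "-"}


def _cluster(family, strand, start, count=8, chrom="chrI"):
    starts = [start + 10 * i for i in range(count)]
    return TECluster(family, chrom, strand, starts, [s + 42 for s in starts])


class TestPairClusters:
    def test_element_length_plus_fragment_separation_is_known(self, catalog):
        fwd = _cluster("Tc1", "+", 1_000)
        # midpoints differ by ~1810 = 1610 + 200
        rev = _cluster("Tc1", "-", 1_000 + 1_810)
        pairs = pair_clusters([fwd, rev], catalog)
        assert pairs[0].status == "known"

    def test_fragment_scale_separation_is_novel(self, catalog):
        pairs = pair_clusters(
            [_cluster("Tc1", "+", 1_000), _cluster("Tc1", "-", 1_250)], catalog
        )
        assert pairs[0].status == "novel"

    def test_intermediate_separation_is_ambiguous(self, catalog):
        pairs = pair_clusters(
            [_cluster("Tc1", "+", 1_000), _cluster("Tc1", "-", 1_900)], catalog
        )
        assert pairs[0].status == "ambiguous"

    def test_lone_cluster_reported_unpaired(self, catalog):
        pairs = pair_clusters([_cluster("Tc2", "+", 1_000)], catalog)
        assert pairs[0].status == "unpaired" and pairs[0].reverse is None


class TestResolution:
    def test_non_novel_pair_rejected(self, catalog, mixed_sim):
        pair = TEClusterPair("Tc1", "chrI", _cluster("Tc1", "+", 0),
                             _cluster("Tc1", "-", 1810), 1810.0, "known")
        with pytest.raises(TEDetectionError):
            resolve_insertion_point(pair, mixed_sim.ref)

    def test_planted_insertions_resolved_exactly(self, mixed_sim):
        calls, pairs = detect_te_insertions(
            mixed_sim.alignments, mixed_sim.catalog, mixed_sim.ref
        )
        truth = {
            (t.family, t.chrom, t.ta_pos) for t in mixed_sim.truth.te_insertions
        }
        called = {
            (c.family, c.chrom, c.position - 1) for c in calls if c.ta_confirmed
        }
        assert called == truth
        for call in calls:
            assert call.status == "novel" and call.ta_confirmed
            ref_seq = mixed_sim.ref[call.chrom]
            t = call.position - 1
            assert ref_seq[t : t + 2] == "TA"
            assert call.left_flank == ref_seq[t - 10 : t]
            assert call.right_flank == ref_seq[t + 2 : t + 12]
            # flanks equal the sample sequence around the planted element
            fam = mixed_sim.catalog[call.family]
            assert (
                call.left_flank + "TA" + fam.sequence[:10]
            ) in mixed_sim.sample[call.chrom]
            assert (
                fam.sequence[-10:] + "TA" + call.right_flank
            ) in mixed_sim.sample[call.chrom]

    def test_flank_string_brackets_the_ta(self, mixed_sim):
        calls, _ = detect_te_insertions(
            mixed_sim.alignments, mixed_sim.catalog, mixed_sim.ref
        )
        s = calls[0].flank_string()
        assert "[TA]" in s and len(s) == 24


@pytest.fixture(scope="module")
def bundle():
    config = SimConfig(
        chromosome_lengths={"chrI": 300_000},
        te_reference_copies={"Tc1": 2},
        te_excisions={"Tc1": 1},
        seed=3,
    )
    catalog = TransposonCatalog.synthetic(seed=3)
    return make_bundle(config, catalog)


class TestKnownCopiesAndExcision:
    def test_remaining_reference_copy_detected_as_known(self, bundle):
        _, pairs = detect_te_insertions(bundle.alignments, bundle.catalog, bundle.ref)
        excised_start = bundle.truth.te_excisions[0].start
        known = [p for p in pairs if p.status == "known"]
        assert len(known) == 1
        retained = [
            (c, s) for c, s in bundle.catalog["Tc1"].reference_copies
            if s != excised_start
        ]
        assert abs(known[0].forward.midpoint - retained[0][1]) < 400

    def test_excised_copy_reported_as_empty_site(self, bundle):
        sites = find_empty_sites(
            collect_unmapped_reads(bundle.alignments), bundle.catalog, bundle.ref
        )
        excision = bundle.truth.te_excisions[0]
        assert len(sites) == 1
        site = sites[0]
        assert (site.family, site.chrom, site.start) == (
            excision.family, excision.chrom, excision.start
        )
        assert site.footprint == "TA" and site.support >= 3

    def test_no_empty_sites_without_excision(self, mixed_sim):
        # plant reference copies via a separate catalog but no excisions
        sites = find_empty_sites(
            collect_unmapped_reads(mixed_sim.alignments),
            mixed_sim.catalog,
            mixed_sim.ref,
        )
        assert sites == []

    def test_junction_needs_minimum_flank_on_both_sides(self, bundle):
        excision = bundle.truth.te_excisions[0]
        seq = bundle.ref[excision.chrom]
        s, e = excision.start, excision.end
        # a read with only 5 bp right of the join must not count
        lopsided = seq[s - 39 : s] + seq[e + 2 : e + 2 + 5]
        assert len(lopsided) == 44 - 2 + 2  # 42 bp
        sites = find_empty_sites([lopsided] * 10, bundle.catalog, bundle.ref)
        assert sites == []


def test_annotate_te_call_feature_strings(mixed_sim):
    calls, _ = detect_te_insertions(
        mixed_sim.alignments, mixed_sim.catalog, mixed_sim.ref
    )
    call = calls[0]
    pos = call.position - 1
    intron_gene = GeneModel(
        "snt-like", call.chrom, "+",
        exons=[(pos - 500, pos - 400), (pos + 400, pos + 501)],
        cds=[(pos - 500, pos - 400), (pos + 400, pos + 501)],
    )
    annotate_te_call(call, [intron_gene])
    assert call.gene_feature == "snt-like intron"
    exon_gene = GeneModel(
        "cod-1", call.chrom, "+",
        exons=[(pos - 10, pos + 92)], cds=[(pos - 10, pos + 92)],
    )
    annotate_te_call(call, [exon_gene])
    assert call.gene_feature == "cod-1 exon"
    annotate_te_call(call, [])
    assert call.gene_feature == "Intergenic"


def test_recall_monotone_in_coverage():
    """Below ~6x the >5-read cluster threshold binds: recall at low
    coverage never exceeds recall at full coverage."""
    recalls = {}
    for coverage in (21.0, 3.0):
        config = SimConfig(
            chromosome_lengths={"chrI": 200_000},
            te_insertions={"Tc1": 2},
            coverage=coverage,
            seed=6,
        )
        catalog = TransposonCatalog.synthetic(seed=6)
        bundle = make_bundle(config, catalog)
        calls, _ = detect_te_insertions(bundle.alignments, catalog, bundle.ref)
        truth = {(t.chrom, t.ta_pos) for t in bundle.truth.te_insertions}
        called = {(c.chrom, c.position - 1) for c in calls if c.ta_confirmed}
        recalls[coverage] = len(truth & called) / len(truth)
    assert recalls[3.0] <= recalls[21.0]
    assert recalls[21.0] == 1.0
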