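"""Shared fixtures: one mid-sized simulation with every event class planted,
mapped once per session, plus small helpers for hand-built alignments."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from recreseq import (
    GenomeIndex,
    ReferenceGenome,
    SimConfig,
    TransposonCatalog,
    derive_sample_genome,
    generate_reference,
    map_read_pairs,
    simulate_pets,
)
from recreseq.mapping import PetAlignment, ReadHalf
from recreseq.simulate import RepeatSpec
from recreseq.spectrum import SPECTRUM_CLASSES


@dataclass
class SimBundle:
    config: SimConfig
    catalog: TransposonCatalog
    ref: ReferenceGenome
    sample: ReferenceGenome
    truth: object
    reads: object
    index: GenomeIndex
    alignments: list


def make_bundle(config: SimConfig, catalog: TransposonCatalog | None = None) -> SimBundle:
    ref = generate_reference(config, catalog)
    sample, truth = derive_sample_genome(ref, config, catalog)
    reads, truth = simulate_pets(sample, config, truth)
    index = GenomeIndex(ref, k=14)
    alignments = map_read_pairs(
        reads, index, 2, expected_span=sum(config.fragment_range) / 2
    )
    return SimBundle(config, catalog, ref, sample, truth, reads, index, alignments)


@pytest.fixture(scope="session")
def mixed_sim() -> SimBundle:
    """300-kb genome with substitutions, TE insertions, a deletion, a small
    insertion and a contracted repeat array, sequenced error-free at 21x."""
    weights = dict(zip(SPECTRUM_CLASSES, (141, 90, 77, 56, 39, 38)))
    config = SimConfig(
        chromosome_lengths={"chrI": 300_000},
        substitutions=30,
        class_weights=weights,
        te_insertions={"Tc1": 2, "Tc2": 1},
        deletion_sizes=[100],
        insertion_sizes=[60],
        repeat_arrays=[RepeatSpec()],
        seed=1,
    )
    catalog = TransposonCatalog.synthetic(seed=1)
    return make_bundle(config, catalog)


@pytest.fixture(scope="session")
def clean_sim() -> SimBundle:
    """Event-free 60-kb simulation (unique sequence, no planted variation)."""
    config = SimConfig(chromosome_lengths={"chrI": 60_000}, seed=9)
    return make_bundle(config)


def make_half(
    chrom: str | None,
    pos: int,
    strand: str = "+",
    seq: str = "A" * 42,
    status: str = "unique",
    mismatches: int = 0,
) -> ReadHalf:
    return ReadHalf(status=status, chrom=chrom, pos=pos, strand=strand,
                    mismatches=mismatches, seq=seq)


def make_pet(
    pair_id: str,
    chrom: str,
    pos1: int,
    pos2: int,
    seq1: str,
    seq2: str,
    read_length: int = 42,
) -> PetAlignment:
    """A proper pair: mate 1 forward at pos1, mate 2 reverse at pos2."""
    r1 = make_half(chrom, pos1, "+", seq1)
    r2 = make_half(chrom, pos2, "-", seq2)
    span = pos2 + read_length - pos1
    return PetAlignment(pair_id, r1, r2, True, span)


def random_genome(length: int, seed: int, name: str = "chrI") -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return ReferenceGenome({name: seq})
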