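"""Synthetic genomes, planted variation and paired-end read simulation.

The generator produces a random multi-chromosome reference, derives a
"mutant" sample genome from it by planting fully recorded events
(substitutions drawn from a six-class spectrum, transposon insertions at TA
dinucleotides with target-site duplication, deletions, small insertions,
contractions of embedded imperfect tandem-repeat arrays and transposon
excisions), and simulates 42-bp paired-end reads from a 180-220 bp fragment
population at a configured fold coverage.  Every event and every read origin
is recorded in a :class:`SimulationTruth` ledger so downstream callers can
be scored against known truth.

Randomness is consumed from three independent streams (reference, sample
events, reads), each seeded from ``SimConfig.seed``, so a given config
reproduces byte-identical FASTA/FASTQ output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .catalog import TransposonCatalog
from .genome import BASES, GenomeError, ReferenceGenome, RepeatLocus, revcomp
from .spectrum import CLASS_CHANGES, SPECTRUM_CLASSES


class SimulationError(ValueError):
    pass


@dataclass
class RepeatSpec:
    """An imperfect tandem direct-repeat array.

    ``copies`` near-identical copies of a random ``unit_length``-bp unit are
    embedded in the reference (each copy independently diverged from the
    unit at rate ``divergence``); the sample genome retains only
    ``sample_copies`` of them, chosen spread across the array so that reads
    straddling the sample's copy junctions land on non-adjacent reference
    copies.  This recreates the classic repeat signature in paired-end data:
    apparent spans longer than normal and of differing sizes, plus a local
    deficit of normally-spaced pairs.
    """

    unit_length: int = 150
    copies: int = 8
    sample_copies: int = 3
    divergence: float = 0.02

    def kept_indices(self) -> list[int]:
        # Deterministically spread the retained copies over the array,
        # skipping the first copy so the leftmost junction is already
        # discordant.  Emulates repeated, independent contraction events.
        if not 0 < self.sample_copies < self.copies:
            raise SimulationError(
                "sample_copies must be between 1 and copies-1 for a contraction"
            )
        picks = np.linspace(1, self.copies - 2, self.sample_copies)
        idx = sorted({int(round(p)) for p in picks})
        while len(idx) < self.sample_copies:  # collisions at tiny arrays
            for j in range(1, self.copies):
                if j not in idx:
                    idx.append(j)
                    break
            idx = sorted(idx)
        return idx


@dataclass
class SimConfig:
    """Configuration of one simulated sequencing experiment.

    Defaults follow the small-insert Illumina design the toolkit targets:
    42-bp paired reads from a 180-220 bp sonicated fraction at 21-fold
    coverage, on an A/T-rich (GC 0.36) multi-chromosome genome.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 500_000, "chrII": 500_000}
    )
    gc: float = 0.36
    substitutions: int = 0
    class_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 / 6 for c in SPECTRUM_CLASSES}
    )
    te_insertions: dict[str, int] = field(default_factory=dict)
    te_reference_copies: dict[str, int] = field(default_factory=dict)
    te_excisions: dict[str, int] = field(default_factory=dict)
    deletion_sizes: list[int] = field(default_factory=list)
    insertion_sizes: list[int] = field(default_factory=list)
    repeat_arrays: list[RepeatSpec] = field(default_factory=list)
    coverage: float = 21.0
    read_length: int = 42
    fragment_range: tuple[int, int] = (180, 220)
    fragment_mean: float | None = None
    fragment_sd: float | None = None
    error_rate: float = 0.0
    seed: int = 0
    # placement controls
    min_event_spacing: int = 5000
    ta_isolation: int = 10

    def __post_init__(self) -> None:
        self.fragment_range = tuple(self.fragment_range)  # type: ignore[assignment]
        if any(L <= 0 for L in self.chromosome_lengths.values()):
            raise GenomeError("chromosome lengths must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise SimulationError("gc must be in [0, 1]")
        counts = [self.substitutions, *self.te_insertions.values(),
                  *self.te_reference_copies.values(), *self.te_excisions.values()]
        if any(c < 0 for c in counts):
            raise SimulationError("event counts must be >= 0")
        if any(s <= 0 for s in list(self.deletion_sizes) + list(self.insertion_sizes)):
            raise SimulationError("deletion/insertion sizes must be positive")
        if self.read_length > min(self.fragment_range):
            raise SimulationError("read length must not exceed the minimum fragment size")
        total = sum(self.class_weights.values())
        if total <= 0:
            raise SimulationError("class weights must have a positive sum")
        if abs(total - 1.0) > 1e-12:  # normalize, but keep it idempotent
            self.class_weights = {c: w / total for c, w in self.class_weights.items()}
        unknown = set(self.class_weights) - set(SPECTRUM_CLASSES)
        if unknown:
            raise SimulationError(f"unknown substitution classes: {sorted(unknown)}")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must be in [0, 1)")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.class_weights.get(c, 0.0) for c in SPECTRUM_CLASSES])

    def rng(self, stream: int) -> np.random.Generator:
        """Independent RNG stream (0=reference, 1=sample events, 2=reads)."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    # --- YAML round trip ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fragment_range"] = list(self.fragment_range)
        data["repeat_arrays"] = [asdict(r) for r in self.repeat_arrays]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "repeat_arrays" in data:
            data["repeat_arrays"] = [
                RepeatSpec(**r) if isinstance(r, dict) else r
                for r in data["repeat_arrays"]
            ]
        if "fragment_range" in data:
            data["fragment_range"] = tuple(data["fragment_range"])
        return cls(**data)


# --------------------------------------------------------------------------
# truth ledger
# --------------------------------------------------------------------------

@dataclass
class Substitution:
    chrom: str
    pos: int          # 0-based reference position
    ref: str
    alt: str


@dataclass
class TEInsertion:
    chrom: str
    ta_pos: int       # 0-based reference position of the TA's T
    family: str
    length: int       # element length (excluding the duplicated TA)


@dataclass
class DeletionEvent:
    chrom: str
    start: int        # 0-based reference start of the removed span
    length: int


@dataclass
class SmallInsertion:
    chrom: str
    start: int        # inserted sequence begins before this reference base
    length: int
    sequence: str


@dataclass
class RepeatContraction:
    chrom: str
    start: int
    unit_length: int
    ref_copies: int
    kept_indices: list[int]

    @property
    def removed_bp(self) -> int:
        return self.unit_length * (self.ref_copies - len(self.kept_indices))


@dataclass
class TEExcision:
    chrom: str
    family: str
    start: int        # element body interval in the reference
    end: int
    footprint: str = "TA"


@dataclass
class ReadOrigins:
    """True origin of every simulated fragment (parallel arrays)."""

    chrom_ids: np.ndarray
    starts: np.ndarray
    frag_lengths: np.ndarray
    strands: np.ndarray     # 0 = fragment read left-to-right as r1, 1 = flipped
    chrom_names: list[str]

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class SimulationTruth:
    """Complete ledger of planted events, the oracle for recovery tests."""

    substitutions: list[Substitution] = field(default_factory=list)
    te_insertions: list[TEInsertion] = field(default_factory=list)
    deletions: list[DeletionEvent] = field(default_factory=list)
    small_insertions: list[SmallInsertion] = field(default_factory=list)
    repeat_contractions: list[RepeatContraction] = field(default_factory=list)
    te_excisions: list[TEExcision] = field(default_factory=list)
    read_origins: ReadOrigins | None = None

    def expected_sample_size(self, ref: ReferenceGenome) -> int:
        """Sample genome length implied by the ledger (conservation check)."""
        size = ref.total_size
        size += sum(t.length + 2 for t in self.te_insertions)
        size += sum(i.length for i in self.small_insertions)
        size -= sum(d.length for d in self.deletions)
        size -= sum(r.removed_bp for r in self.repeat_contractions)
        for x in self.te_excisions:
            removed = x.end - x.start + 4 - len(x.footprint)
            size -= removed
        return size

    # --- serialization --------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("event\tchrom\tpos\tfields\n")
            for s in self.substitutions:
                fh.write(f"substitution\t{s.chrom}\t{s.pos + 1}\t{s.ref}>{s.alt}\n")
            for t in self.te_insertions:
                fh.write(f"te_insertion\t{t.chrom}\t{t.ta_pos + 1}\t{t.family};{t.length}\n")
            for d in self.deletions:
                fh.write(f"deletion\t{d.chrom}\t{d.start + 1}\t{d.length}\n")
            for i in self.small_insertions:
                fh.write(f"insertion\t{i.chrom}\t{i.start + 1}\t{i.length};{i.sequence}\n")
            for r in self.repeat_contractions:
                kept = ",".join(map(str, r.kept_indices))
                fh.write(
                    f"repeat_contraction\t{r.chrom}\t{r.start + 1}\t"
                    f"{r.unit_length};{r.ref_copies};{kept}\n"
                )
            for x in self.te_excisions:
                fh.write(
                    f"te_excision\t{x.chrom}\t{x.start + 1}\t"
                    f"{x.family};{x.end - x.start};{x.footprint}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimulationTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("event\t"):
                raise SimulationError(f"malformed truth file {path}")
            for line in fh:
                event, chrom, pos, rest = line.rstrip("\n").split("\t")
                p = int(pos) - 1
                if event == "substitution":
                    ref, alt = rest.split(">")
                    truth.substitutions.append(Substitution(chrom, p, ref, alt))
                elif event == "te_insertion":
                    fam, length = rest.split(";")
                    truth.te_insertions.append(TEInsertion(chrom, p, fam, int(length)))
                elif event == "deletion":
                    truth.deletions.append(DeletionEvent(chrom, p, int(rest)))
                elif event == "insertion":
                    length, seq = rest.split(";")
                    truth.small_insertions.append(SmallInsertion(chrom, p, int(length), seq))
                elif event == "repeat_contraction":
                    unit, copies, kept = rest.split(";")
                    truth.repeat_contractions.append(
                        RepeatContraction(
                            chrom, p, int(unit), int(copies),
                            [int(k) for k in kept.split(",")],
                        )
                    )
                elif event == "te_excision":
                    fam, length, footprint = rest.split(";")
                    truth.te_excisions.append(
                        TEExcision(chrom, fam, p, p + int(length), footprint)
                    )
                else:
                    raise SimulationError(f"unknown truth event {event!r}")
        return truth

    def to_vcf(self, ref: ReferenceGenome, path: str | Path) -> None:
        """Substitutions and deletions as planted-truth VCF."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##source=recreseq-truth\n")
            for name, length in ref.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            rows = []
            for s in self.substitutions:
                rows.append((s.chrom, s.pos + 1, s.ref, s.alt, "TYPE=substitution"))
            for d in self.deletions:
                anchor_pos = d.start - 1
                seq = ref[d.chrom][anchor_pos : d.start + d.length]
                rows.append((d.chrom, anchor_pos + 1, seq, seq[0], "TYPE=deletion"))
            order = {n: i for i, n in enumerate(ref.names)}
            rows.sort(key=lambda r: (order[r[0]], r[1]))
            for chrom, pos, r, a, info in rows:
                fh.write(f"{chrom}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t{info}\n")

    def to_bed(self, path: str | Path) -> None:
        """TE insertions and repeat contractions as planted-truth BED."""
        with open(path, "w") as fh:
            for t in self.te_insertions:
                fh.write(f"{t.chrom}\t{t.ta_pos}\t{t.ta_pos + 2}\tte_insertion:{t.family}\n")
            for r in self.repeat_contractions:
                end = r.start + r.unit_length * r.ref_copies
                fh.write(f"{r.chrom}\t{r.start}\t{end}\trepeat_array\n")


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode()


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    hits = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def generate_reference(
    config: SimConfig, catalog: TransposonCatalog | None = None
) -> ReferenceGenome:
    """Generate a random reference genome per ``config``.

    Tandem-repeat arrays from ``config.repeat_arrays`` are embedded in the
    sequence (recorded in ``ReferenceGenome.repeat_arrays``), and if a
    ``catalog`` with requested ``config.te_reference_copies`` is given,
    element copies (with TA flanks) are written into the reference and
    their positions recorded on the catalog families in place.
    """
    for name, L in config.chromosome_lengths.items():
        if L < 10_000:
            raise GenomeError(f"chromosome {name!r} shorter than 10 kbp ({L})")
    rng = config.rng(0)
    chrom_codes = {
        name: _random_dna(rng, L, config.gc)
        for name, L in config.chromosome_lengths.items()
    }
    names = list(chrom_codes)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    spacing = config.min_event_spacing

    def reserve(length: int) -> tuple[str, int]:
        for _ in range(2000):
            name = names[rng.integers(len(names))]
            L = len(chrom_codes[name])
            if L < length + 2 * spacing:
                continue
            start = int(rng.integers(spacing, L - length - spacing))
            if all(
                start >= e + spacing or start + length <= s - spacing
                for s, e in placed[name]
            ):
                placed[name].append((start, start + length))
                return name, start
        raise SimulationError(
            f"could not place a {length}-bp feature with {spacing}-bp spacing"
        )

    repeat_loci: list[RepeatLocus] = []
    for spec in config.repeat_arrays:
        array_len = spec.unit_length * spec.copies
        name, start = reserve(array_len)
        unit = _random_dna(rng, spec.unit_length, config.gc)
        copies = [_mutate(rng, unit, spec.divergence) for _ in range(spec.copies)]
        chrom_codes[name][start : start + array_len] = np.concatenate(copies)
        repeat_loci.append(RepeatLocus(name, start, spec.unit_length, spec.copies))

    if catalog is not None:
        from .genome import encode
        for fam_name, count in config.te_reference_copies.items():
            fam = catalog[fam_name]
            fam.reference_copies = []
            elem = encode("TA" + fam.sequence + "TA")
            for _ in range(count):
                name, start = reserve(len(elem))
                chrom_codes[name][start : start + len(elem)] = elem
                fam.reference_copies.append((name, start + 2))

    genome = ReferenceGenome(
        {name: _codes_to_str(codes) for name, codes in chrom_codes.items()},
        repeat_arrays=repeat_loci,
    )
    _check_ta_supply(genome, config)
    return genome


def _ta_positions(seq: str) -> np.ndarray:
    from .genome import encode
    codes = encode(seq)
    return np.nonzero((codes[:-1] == 3) & (codes[1:] == 0))[0]


def _check_ta_supply(genome: ReferenceGenome, config: SimConfig) -> None:
    need = 10 * sum(config.te_insertions.values())
    if need == 0:
        return
    for name in genome.names:
        n_ta = len(_ta_positions(genome[name]))
        if n_ta < need:
            raise SimulationError(
                f"chromosome {name} has only {n_ta} TA sites; need >= {need}"
            )


# --------------------------------------------------------------------------
# sample derivation
# --------------------------------------------------------------------------

def _isolated_ta_positions(seq: str, margin: int) -> np.ndarray:
    """TA dinucleotide starts with no other TA start within ``margin`` bp.

    Insertion sites restricted to locally unique TAs keep the insertion
    point resolvable from read evidence; TA-dense microsatellite contexts
    are exactly the ones real callers report as ambiguous.
    """
    ta = _ta_positions(seq)
    if len(ta) == 0:
        return ta
    gap_left = np.diff(ta, prepend=-(10 * margin))
    gap_right = np.diff(ta, append=len(seq) + 10 * margin)
    return ta[(gap_left > margin) & (gap_right > margin)]


def derive_sample_genome(
    ref: ReferenceGenome,
    config: SimConfig,
    catalog: TransposonCatalog | None = None,
) -> tuple[ReferenceGenome, SimulationTruth]:
    """Plant the configured events into a copy of ``ref``.

    Returns the sample genome and the complete truth ledger.  All truth
    coordinates are in the reference frame.  Transposon insertions follow
    the TA target-site duplication convention: the reference TA is
    duplicated so the element is flanked by TA on both sides of the sample
    genome.
    """
    rng = config.rng(1)
    truth = SimulationTruth()
    names = ref.names
    rl = config.read_length
    spacing = config.min_event_spacing

    need_catalog = (config.te_insertions or config.te_excisions)
    if need_catalog and catalog is None:
        raise SimulationError("TE insertions/excisions requested but no catalog given")

    # structural intervals blocked per chromosome: (start, end)
    blocked: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for locus in ref.repeat_arrays:
        blocked[locus.chrom].append((locus.start, locus.end))
    if catalog is not None:
        for fam in catalog:
            for chrom, start in fam.reference_copies:
                blocked[chrom].append((start - 2, start + fam.length + 2))

    def is_free(chrom: str, start: int, end: int) -> bool:
        return all(
            start >= e + spacing or end <= s - spacing for s, e in blocked[chrom]
        )

    def reserve_at(chrom: str, start: int, end: int) -> None:
        blocked[chrom].append((start, end))

    def pick_interval(length: int, what: str) -> tuple[str, int]:
        for _ in range(5000):
            chrom = names[rng.integers(len(names))]
            L = len(ref[chrom])
            if L < length + 2 * spacing:
                continue
            start = int(rng.integers(spacing, L - length - spacing))
            if is_free(chrom, start, start + length):
                reserve_at(chrom, start, start + length)
                return chrom, start
        raise SimulationError(f"could not place {what} (non-overlap exhausted)")

    # --- transposon insertions at isolated TA sites ---------------------
    iso_ta = {
        n: _isolated_ta_positions(ref[n], config.ta_isolation) for n in names
    }
    structural: dict[str, list[tuple[int, int, str]]] = {n: [] for n in names}

    for fam_name, count in config.te_insertions.items():
        fam = catalog[fam_name]
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 20000:
                raise SimulationError(
                    f"insufficient non-overlapping TA sites for {fam_name}: "
                    f"placed {placed} of {count}"
                )
            chrom = names[rng.integers(len(names))]
            sites = iso_ta[chrom]
            if len(sites) == 0:
                continue
            t = int(sites[rng.integers(len(sites))])
            L = len(ref[chrom])
            if t < spacing or t + 2 + spacing > L:
                continue
            if not is_free(chrom, t, t + 2):
                continue
            reserve_at(chrom, t, t + 2)
            structural[chrom].append((t, t + 2, "TA" + fam.sequence + "TA"))
            truth.te_insertions.append(TEInsertion(chrom, t, fam_name, fam.length))
            placed += 1

    # --- deletions ------------------------------------------------------
    for size in config.deletion_sizes:
        chrom, start = pick_interval(size, f"{size}-bp deletion")
        structural[chrom].append((start, start + size, ""))
        truth.deletions.append(DeletionEvent(chrom, start, size))

    # --- small novel-sequence insertions --------------------------------
    for size in config.insertion_sizes:
        chrom, start = pick_interval(1, f"{size}-bp insertion")
        seq = _codes_to_str(_random_dna(rng, size, config.gc))
        structural[chrom].append((start, start, seq))
        truth.small_insertions.append(SmallInsertion(chrom, start, size, seq))

    # --- repeat-array contractions --------------------------------------
    spec_by_key = {}
    for spec, locus in zip(config.repeat_arrays, ref.repeat_arrays):
        spec_by_key[(locus.chrom, locus.start)] = spec
    for locus in ref.repeat_arrays:
        spec = spec_by_key.get((locus.chrom, locus.start))
        if spec is None or spec.sample_copies >= spec.copies:
            continue
        kept = spec.kept_indices()
        u = locus.unit_length
        seq = ref[locus.chrom]
        sample_array = "".join(
            seq[locus.start + i * u : locus.start + (i + 1) * u] for i in kept
        )
        structural[locus.chrom].append((locus.start, locus.end, sample_array))
        truth.repeat_contractions.append(
            RepeatContraction(locus.chrom, locus.start, u, locus.copies, kept)
        )

    # --- transposon excisions (empty-site footprints) -------------------
    if catalog is not None:
        for fam_name, count in config.te_excisions.items():
            fam = catalog[fam_name]
            if count > len(fam.reference_copies):
                raise SimulationError(
                    f"{fam_name}: {count} excisions requested but only "
                    f"{len(fam.reference_copies)} reference copies exist"
                )
            order = rng.permutation(len(fam.reference_copies))[:count]
            for i in sorted(order):
                chrom, start = fam.reference_copies[int(i)]
                end = start + fam.length
                # reference carries TA | element | TA; excision leaves a
                # single TA footprint (left TA retained)
                structural[chrom].append((start, end + 2, ""))
                truth.te_excisions.append(
                    TEExcision(chrom, fam_name, start, end, footprint="TA")
                )

    # --- substitutions from the six-class spectrum ----------------------
    if config.substitutions:
        counts = rng.multinomial(config.substitutions, config.weight_vector)
        used: set[tuple[str, int]] = set()

        def site_ok(chrom: str, pos: int) -> bool:
            if (chrom, pos) in used:
                return False
            lo, hi = pos - rl, pos + 1 + rl
            for s, e, _repl in structural[chrom]:
                if lo < e and s < hi:
                    return False
            for s, e in blocked[chrom]:
                if lo < e and s < hi:
                    return False
            return True

        sizes = np.array([len(ref[n]) for n in names], dtype=float)
        chrom_p = sizes / sizes.sum()
        for label, n_class in zip(SPECTRUM_CLASSES, counts):
            changes = CLASS_CHANGES[label]
            placed = 0
            attempts = 0
            while placed < n_class:
                attempts += 1
                if attempts > 200000:
                    raise SimulationError(
                        f"could not place substitutions of class {label}"
                    )
                ref_base, alt_base = changes[rng.integers(2)]
                chrom = names[rng.choice(len(names), p=chrom_p)]
                pos = int(rng.integers(rl, len(ref[chrom]) - rl))
                if ref[chrom][pos] != ref_base or not site_ok(chrom, pos):
                    continue
                used.add((chrom, pos))
                truth.substitutions.append(Substitution(chrom, pos, ref_base, alt_base))
                placed += 1

    # --- build the sample genome ---------------------------------------
    sample_chroms: dict[str, str] = {}
    subs_by_chrom: dict[str, list[Substitution]] = {n: [] for n in names}
    for s in truth.substitutions:
        subs_by_chrom[s.chrom].append(s)
    for name in names:
        seq = bytearray(ref[name], "ascii")
        for s in subs_by_chrom[name]:
            assert seq[s.pos : s.pos + 1].decode() == s.ref
            seq[s.pos] = ord(s.alt)
        events = sorted(structural[name])
        for i in range(1, len(events)):
            if events[i][0] < events[i - 1][1]:
                raise SimulationError(f"overlapping structural events on {name}")
        pieces = []
        cursor = 0
        for start, end, replacement in events:
            pieces.append(seq[cursor:start].decode())
            pieces.append(replacement)
            cursor = end
        pieces.append(seq[cursor:].decode())
        sample_chroms[name] = "".join(pieces)

    sample = ReferenceGenome(sample_chroms)
    assert sample.total_size == truth.expected_sample_size(ref)
    return sample, truth


# --------------------------------------------------------------------------
# paired-end read simulation
# --------------------------------------------------------------------------

@dataclass
class PairedReads:
    """Simulated read pairs; mate 2 is the reverse complement of the
    fragment's other end."""

    r1: list[str]
    r2: list[str]

    def __len__(self) -> int:
        return len(self.r1)

    def names(self) -> list[str]:
        return [f"pair{i}" for i in range(len(self.r1))]


def expected_pair_count(coverage: float, genome_size: int, read_length: int) -> int:
    return math.ceil(coverage * genome_size / (2 * read_length))


def simulate_pets(
    sample: ReferenceGenome,
    config: SimConfig,
    truth: SimulationTruth | None = None,
) -> tuple[PairedReads, SimulationTruth]:
    """Simulate paired-end tags from the sample genome.

    Fragment lengths are uniform over ``config.fragment_range`` (or normal
    with ``fragment_mean``/``fragment_sd`` when given, clipped to valid
    sizes); fragment positions are uniform over the genome; each fragment
    is sequenced from a random strand.  Per-base errors substitute a
    uniformly chosen different base.  True origins are recorded in the
    truth ledger.
    """
    if config.coverage <= 0:
        raise SimulationError("coverage must be positive")
    if truth is None:
        truth = SimulationTruth()
    rng = config.rng(2)
    rl = config.read_length
    names = sample.names
    lengths = np.array([len(sample[n]) for n in names])
    n_pairs = expected_pair_count(config.coverage, int(lengths.sum()), rl)
    per_chrom = rng.multinomial(n_pairs, lengths / lengths.sum())

    fmin, fmax = config.fragment_range
    all_chrom_ids = []
    all_starts = []
    all_frags = []
    all_strands = []
    r1: list[str] = []
    r2: list[str] = []

    for ci, (name, n_c) in enumerate(zip(names, per_chrom)):
        if n_c == 0:
            continue
        L = int(lengths[ci])
        if config.fragment_mean is not None:
            frags = np.rint(
                rng.normal(config.fragment_mean, config.fragment_sd or 0.0, size=n_c)
            ).astype(np.int64)
            frags = np.clip(frags, rl, min(L, 10 * int(config.fragment_mean)))
        else:
            frags = rng.integers(fmin, fmax + 1, size=n_c)
        frags = np.minimum(frags, L)
        starts = (rng.random(n_c) * (L - frags + 1)).astype(np.int64)
        strands = rng.integers(0, 2, size=n_c).astype(np.int8)
        if config.error_rate > 0:
            n_err = rng.binomial(rl, config.error_rate, size=(n_c, 2))
        else:
            n_err = None
        seq = sample[name]
        for j in range(n_c):
            s = int(starts[j])
            F = int(frags[j])
            left = seq[s : s + rl]
            right = revcomp(seq[s + F - rl : s + F])
            if n_err is not None:
                if n_err[j, 0]:
                    left = _inject_errors(rng, left, int(n_err[j, 0]))
                if n_err[j, 1]:
                    right = _inject_errors(rng, right, int(n_err[j, 1]))
            if strands[j] == 0:
                r1.append(left)
                r2.append(right)
            else:
                r1.append(right)
                r2.append(left)
        all_chrom_ids.append(np.full(n_c, ci, dtype=np.int32))
        all_starts.append(starts)
        all_frags.append(frags.astype(np.int32))
        all_strands.append(strands)

    truth.read_origins = ReadOrigins(
        chrom_ids=np.concatenate(all_chrom_ids) if all_chrom_ids else np.empty(0, np.int32),
        starts=np.concatenate(all_starts) if all_starts else np.empty(0, np.int64),
        frag_lengths=np.concatenate(all_frags) if all_frags else np.empty(0, np.int32),
        strands=np.concatenate(all_strands) if all_strands else np.empty(0, np.int8),
        chrom_names=names,
    )
    return PairedReads(r1, r2), truth


def _inject_errors(rng: np.random.Generator, seq: str, k: int) -> str:
    out = bytearray(seq, "ascii")
    positions = rng.integers(0, len(seq), size=k)
    shifts = rng.integers(1, 4, size=k)
    lut = {ord(b): i for i, b in enumerate(BASES)}
    for p, d in zip(positions, shifts):
        out[p] = ord(BASES[(lut[out[p]] + int(d)) % 4])
    return out.decode()


# --------------------------------------------------------------------------
# FASTQ I/O
# --------------------------------------------------------------------------

def write_fastq(reads: PairedReads, path1: str | Path, path2: str | Path) -> None:
    """Write mates to two FASTQ files with /1 and /2 name suffixes.

    Qualities are constant (quality-aware logic is out of scope).
    """
    for path, mate, suffix in ((path1, reads.r1, "/1"), (path2, reads.r2, "/2")):
        with open(path, "w") as fh:
            for i, seq in enumerate(mate):
                fh.write(f"@pair{i}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> PairedReads:
    def load(path):
        seqs = []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seqs.append(fh.readline().strip().upper())
                fh.readline()
                fh.readline()
        return seqs

    r1, r2 = load(path1), load(path2)
    if len(r1) != len(r2):
        raise SimulationError("mate files have different read counts")
    return PairedReads(r1, r2)
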