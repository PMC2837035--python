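# Methods

This note documents the models and procedures implemented in `recreseq`,
the parameters that matter, what the simulator does and does not emulate,
and the design choices made where the design was genuinely open.

## Study design being modelled

The package models a whole-genome shotgun resequencing experiment on a
homozygous, self-fertilising organism: one mutant strain compared against
one reference genome. Sequencing is paired-end tags (PETs) — 42-bp reads
from both ends of gel-size-selected 180–220-bp fragments — at roughly
21-fold coverage. All analyses work from three measurable quantities per
read pair: mapped positions, strands and mismatch counts; and from one
derived quantity, the *apparent span* (reference distance between the
outermost mapped ends of a proper pair).

## Synthetic data generator

`SimConfig` fixes the experiment: chromosome lengths, GC fraction (default
0.36, the A/T-rich composition typical of the *C. elegans* genome), event
counts, coverage (21×), read length (42 bp), fragment range (uniform
180–220 bp, matching a gel excision; a normal model with mean/sd is
available), per-base error rate (default 0, errors substitute a uniformly
chosen different base), and a seed. Three independent RNG streams
(reference, sample events, reads) derive from the seed, so identical
configs give byte-identical FASTA/FASTQ/truth output.

Event classes planted into the sample genome (all truth coordinates are in
the reference frame; internal coordinates are 0-based half-open, reports
1-based):

* **Substitutions** drawn from configurable six-class spectrum weights;
  within a class, the two strand-specific changes are equiprobable. Sites
  keep one read length clear of structural events so substitution recovery
  is not confounded by junction effects.
* **Transposon insertions** follow the TA target-site duplication
  convention of the Tc1/mariner superfamily: the reference `…L TA R…`
  becomes `…L TA <element> TA R…` in the sample (+element length + 2 bp).
  Insertion sites are drawn from *locally isolated* TA dinucleotides (no
  other TA start within ±10 bp, `ta_isolation`). This is a deliberate study
  condition: at TA-dense microsatellite sites the insertion point is
  genuinely unresolvable to the base — real analyses report such sites as
  "ambiguous insertion point" — so the generator's defaults plant resolvable
  sites and the ambiguity path is exercised separately.
* **Deletions** remove exact spans (default test case ~100 bp, the scale of
  the intergenic deletion such studies detect from long PETs).
* **Small insertions** of novel sequence (sub-fragment scale, e.g. 60 bp)
  exercise the short-PET insertion signature. Insertions much larger than
  the fragment size produce no spanning pairs and are the transposon
  caller's job, not the span analyser's.
* **Imperfect direct-repeat arrays**: the *reference* carries `copies`
  (default 8) tandem copies of a random `unit_length` (150 bp) unit, each
  independently diverged from the unit at `divergence` (2% — the paper
  family of analyses never states this value; it is exposed as config).
  The sample retains `sample_copies` (3) of them, chosen deterministically
  spread across the array to emulate multiple independent contraction
  events. This asymmetry is what produces the repeat signature: mates
  landing in the array map to non-adjacent reference copies, giving long
  apparent spans *of differing sizes*, while most array reads are
  multi-mapped or junction-crossing, leaving a deficit of normally-spaced
  pairs. A single contiguous contraction would instead mimic a clean
  deletion — constant span shift — which is exactly the initial
  misreading the signature was defined to resolve.
* **Reference element copies and excisions**: catalog elements can be
  embedded in the reference (TA-flanked) and excised from the sample,
  leaving a joined `L TA R` footprint for the empty-site search.

Structural events are placed by rejection sampling with a minimum spacing
(default 5 kb) so clusters from different events cannot merge. Read pairs:
`ceil(coverage × genome / (2 × read length))` fragments, positions uniform,
strand random, mate 2 reported as the reverse complement of the fragment's
far end; every origin is recorded.

What the simulator does **not** emulate: base-quality variation (qualities
are constant; quality-aware logic is out of scope), indel sequencing
errors, PCR duplicates, GC-coverage bias, heterozygosity, and real genomic
repeat structure beyond the planted arrays. Passing recovery tests
therefore demonstrate correctness of the *algorithms* under the stated
read model, not calibrated performance on real libraries.

## Read mapping

Pigeonhole seed-and-verify, ungapped: a read is split into
`max_mismatches + 1` disjoint k-mers (k = 14 by default; 3 × 14 ≤ 42), so
any alignment within the mismatch budget contains at least one exact seed.
Seeds are looked up in a sorted k-mer table over the forward strand
(reverse-strand hits search the read's reverse complement) and every
candidate locus is verified by a full Hamming comparison — the mapper is
exact by construction, and the test suite checks it against an independent
all-positions Hamming scan. N bases mismatch everything. A read is
`unique` when exactly one locus attains the best distance, `multi`
otherwise, `unmapped` when nothing is within budget.

Pairing: a proper pair has both mates on one chromosome, opposite strands,
inward orientation; its span is rightmost end − leftmost start. When a
mate is multi-mapped, the combination of best-distance loci whose span is
closest to the expected span (midpoint of the fragment range) is chosen if
the minimiser is unique; the mate keeps its `multi` status either way.
Multi-mapped reads are excluded from the pileup and from span anomaly
detection (this mirrors the poor effective coverage of repeats) but their
sequences are retained, as are unmapped mates, for the transposon caller.
The implementation is vectorised over read batches (binary-searched seed
table, array Hamming verification); a 2-Mbp, 21× run (~500k pairs) maps in
tens of seconds on one CPU.

SAM I/O uses standard flags; NM carries the mismatch count and a custom XT
tag the unique/multi/unmapped status so files round-trip losslessly.

## Substitution calling and spectrum statistics

The pileup consensus caller assumes a homozygous sample: a site is called
iff depth ≥ `min_depth` (4) and the most frequent non-reference base has
fraction ≥ `min_fraction` (0.8). The original analyses intersected two
external callers; both are out of scope here, and the downstream statistics
only require a call set, so one documented caller with exposed thresholds
stands in. At 21× error-free coverage the caller recovers planted
substitutions exactly; with 1% per-base error, sensitivity stays ≥ 99% in
the test conditions. Edge artifacts can appear within a read length of
structural-event junctions (e.g. positions inside a deletion have no true
coverage, so the few junction-overhang reads that map with ≤ 2 mismatches
can dominate a low-depth pileup).

Classification maps the 12 strand-specific changes onto 6 classes by
complement symmetry. Ts/Tv = (G:C→A:T + A:T→G:C) / (A:T→T:A + G:C→T:A +
A:T→C:G + G:C→C:G); undefined (reported NA) without transversions. Display
formatting follows the conventional mixed precision of published
per-chromosome tables — two decimals with a trailing zero stripped — which
reproduces rows like `2.1 0.5 0.5 0.6 0.48 1.07 0.81` exactly; stored
values are full precision.

Regional density divides call counts by region span in Mbp (2-decimal
report). The denominators use the *span* of the supplied arm/cluster
region map, not aligned bp; region boundaries are required input and never
hard-coded. Annotation uses interval containment with precedence
CDS > UTR > intron > intergenic and decides synonymy by translating the
affected codon under the standard genetic code, using the CDS frame and
strand (CDS lengths must be divisible by 3; violations are model errors).

`run_summary` reports round(100 × aligned/total)% and
round(aligned × read length / genome size)-fold coverage.

## Insert-size anomaly detection

Fragment statistics are the 1%-trimmed mean and sd of proper unique-pair
spans (≥ 100 pairs required). Pairs outside mean ± k·sd ± slack (k = 3,
slack = 10 bp) are flagged short or long; same-direction flagged pairs
whose inner intervals lie within `max_gap` (50 bp) form single-linkage
clusters, and clusters need ≥ 3 members. The published description gives
no numeric threshold ("outside the normal size range"); k = 3 with 3
supporting pairs is chosen so an event-free 21× simulation yields zero
false positives (verified over 10 seeds), and both are config.

Classification: short cluster → insertion, size = normal mean − member
span mean; long cluster with span coefficient of variation ≤ 0.1 →
deletion, size = member span mean − normal mean; long cluster with CV >
0.1 *and* local normal-pair coverage below 25% of the genome median →
direct repeat (no size estimate); otherwise unclassified-long. Size
estimates are within ±10 bp for 50–150-bp deletions at 21×; insertions are
limited to events smaller than (max fragment − 2 × read length) ≈ 136 bp,
above which no spanning pairs exist. How the original ~100-bp deletion's
size was estimated is not stated in the source analyses; the span-shift
mean is this package's documented choice. Inversion/translocation calling
is not implemented (the signature exists but the studies report none).

## Transposon insertion detection

1. **Terminus match**: pairs with a uniquely mapped anchor whose mate is
   unmapped, multi-mapped, or mapped within a known catalog copy are
   searched against both strands of the first and last 300 bp (`window`)
   of each canonical element; ≤ 2 mismatches at any offset is a hit.
2. **Clustering**: same-family, same-strand anchors within the maximum
   fragment size chain into clusters; clusters need more than five reads
   (≥ 6, reading the published "more than five" strictly).
3. **Pairing**: forward clusters pair greedily with the nearest downstream
   reverse cluster. Midpoint separation ≈ element length + 200 bp (±100 bp
   tolerance) → known reference copy; within 200–300 bp (± tolerance) →
   novel insertion; otherwise ambiguous; leftovers are reported unpaired
   rather than dropped. The tolerance is a config default — the source
   description says only "approximating" and "about".
4. **TA resolution**: for a novel pair, the insertion point is the TA
   dinucleotide between the innermost read boundaries ± 5 bp. Coverage
   gaps, or anchors that overrun the junction because the element start
   happens to resemble the reference, can leave zero or several candidates
   in that window; candidates over a widened window are then disambiguated
   by *junction reads* — each candidate TA predicts exact
   flank+element junction strings on both sides, and unmapped reads are
   matched against them (≥ 3 bases across the join). Only the true site
   collects support in error-free data; this is the in-silico version of
   reading the partially-element-matching reads at the insertion site.
   Remaining ties give an ambiguous call with no flank report. A confirmed
   call reports the 1-based position of the TA's T, 10-bp flanks either
   side, and per-strand supporting read counts.
5. **Empty sites**: for each known reference copy, the excision junction
   (left flank + TA or TATA footprint + right flank) is searched in
   unmapped reads; ≥ 3 reads matching with ≥ 15 bp on each side of the
   join report the copy as vacated. A literal search for "TA"/"TATA" in
   reads is degenerate (TA occurs in nearly every read); anchoring the
   search to known copies is the only interpretation that can find vacated
   sites, and is implemented as such.

At 21× error-free coverage on a 2-Mbp genome, all planted insertions (11
Tc1-like + 8 Tc2-like) are called novel and TA-confirmed at their exact
planted positions with zero spurious calls; recall degrades below ~6×
where the > 5-read cluster threshold binds. Identifying the progenitor
copy of an insertion (element-internal variants) is out of scope.

## Pipeline and reproducibility

`run_pipeline` chains simulate → map → call-snv → call-sv → call-te →
report, logging per-stage counts, and writes plain-text artifacts only
(FASTA 60-column, paired FASTQ, SAM, VCF 4.2, BED, TSV) plus a manifest
with the config snapshot, seed and SHA-256 digests of every output. One
seed drives three per-stage RNG streams, so reruns are byte-identical.
The recovery report scores calls against the truth ledger: substitutions
must match exactly; other event classes within 10 bp.

## Problem sizes used in the checks

The published genome-wide counts come from ~60 million reads over a
100-Mbp genome and are not re-derivable from desk-scale simulation;
worked-example checks therefore use the published count *table* as input,
and recovery checks run at reduced scale chosen to preserve the signal
geometry: 2 Mbp / ~500k pairs for transposon recovery (the paper-scale
event density), 100–300 kb for SV and spectrum recovery, 10 seeds of
event-free 100-kb runs for the false-positive check, and a 50-kb genome
with 1,000 reads for the mapper-vs-brute-force equivalence oracle.

## Known limitations

* Ungapped mapping: small indels in reads are not representable; real
  aligner behaviour near indels is out of scope.
* The pileup caller has no genotype model beyond homozygous consensus.
* Span-based insertion sizing saturates near the fragment size; TE-length
  insertions are detectable only through the terminus pipeline.
* The direct-repeat classifier keys on span dispersion plus coverage
  deficit; a repeat region whose sample and reference structure happen to
  differ by one contiguous block will be classified as a deletion, which
  is the honest reading of the evidence.
* Empty-site search needs the element catalog to list reference copies;
  it cannot discover vacated sites of unknown elements.
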