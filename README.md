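# recreseq

Paired-end short-read resequencing analysis of a mutant genome against its
reference, built around fully simulated data with a recorded truth ledger.
The package targets the classic small-insert Illumina design used for the
first *C. elegans* mutant-strain genome sequences: 42-bp paired-end tags
(PETs) from a gel-excised 180–220-bp fragment population at ~21-fold
coverage, aligned with at most two mismatches per read.

It is aimed at people who want a transparent, end-to-end testable
implementation of the core analyses of such a study:

* **Base-substitution calling and spectrum statistics** — a pileup
  consensus caller for homozygous samples; classification of calls into the
  six nonstrand-specific substitution classes (G:C→A:T, A:T→T:A, G:C→T:A,
  A:T→G:C, A:T→C:G, G:C→C:G, pooling each change with its reverse
  complement); per-chromosome count tables with transition/transversion
  ratios Ts/Tv = (G:C→A:T + A:T→G:C) / (other four classes); regional
  densities (differences per Mbp) and exon/UTR/intron/intergenic annotation
  with codon-level synonymy.
* **Insert-size anomaly (SV) detection** — with a tight fragment-size
  selection, the apparent reference span of a proper pair is a ruler across
  the sequenced fragment. Insertions in the sample *shorten* apparent
  spans, deletions *lengthen* them, and imperfect tandem direct repeats
  produce long spans of differing sizes over an interval lacking
  normally-spaced pairs. Clusters of spans outside mean ± k·sd are
  classified accordingly, with size estimates from the span shift.
* **Transposon insertion detection** — read pairs with one uniquely mapped
  anchor and a mate matching 300 bp of the 5′ or 3′ end of a canonical
  element (e.g. Tc1: 1,610 bp with 54-bp terminal inverted repeats; Tc2:
  2,074 bp with perfect 24-bp TIRs) are clustered by anchor strand. A
  forward cluster upstream and reverse cluster downstream separated by
  roughly the element length + 200 bp mark a copy already in the reference;
  a separation of about 200–300 bp marks a novel insertion. The TA target
  dinucleotide (duplicated on insertion, so the element is TA-flanked on
  both sides) is resolved to the base from the innermost reads, with
  junction-read confirmation; an empty-site search scans unmapped reads for
  the joined flanks (TA/TATA footprint) of excised elements.
* **Synthetic data with planted truth** — a seeded generator producing a
  reference genome, a derived mutant carrying substitutions from a
  configurable six-class spectrum, TE insertions at TA dinucleotides,
  ~100-bp deletions, small insertions and contracted imperfect repeat
  arrays, plus simulated paired-end reads. Every event and read origin is
  recorded, so each caller is scored against exact truth.

The read mapper is a deliberately transparent stand-in for production
aligners: pigeonhole seeding (a read split into *m*+1 disjoint exact
k-mers must leave one seed untouched by ≤ *m* mismatches) with full
Hamming verification, no indels.

## Worked example

```python
from recreseq import *
from recreseq.simulate import SimConfig, RepeatSpec

cfg = SimConfig(
    chromosome_lengths={"chrI": 300_000},
    substitutions=30,
    te_insertions={"Tc1": 2, "Tc2": 1},
    deletion_sizes=[100],
    repeat_arrays=[RepeatSpec()],   # 8 imperfect copies, sample keeps 3
    seed=1,
)
catalog = TransposonCatalog.synthetic(seed=1)
ref = generate_reference(cfg, catalog)
sample, truth = derive_sample_genome(ref, cfg, catalog)
reads, truth = simulate_pets(sample, cfg, truth)

index = GenomeIndex(ref, k=14)
alignments = map_read_pairs(reads, index, max_mismatches=2, expected_span=200)

print(build_spectrum(pileup_consensus(alignments, ref), ref).to_frame())
sv_calls, stats = detect_svs(alignments, ref)
te_calls, _ = detect_te_insertions(alignments, catalog, ref)
```

prints the spectrum table

```
            chrI Total
G:C to A:T     6     6
A:T to T:A     3     3
G:C to T:A     7     7
A:T to G:C     1     1
A:T to C:G     4     4
G:C to C:G    10    10
Total         31    31
Ts/Tv       0.29  0.29
```

(31 calls: the 30 planted substitutions plus one pileup artifact at the
deletion junction, where reference positions inside the deletion have no
true coverage), the SV calls

```
fragment spans: mean 200.1 bp, sd 11.6 bp
direct_repeat  chrI:6982-8436    size NA      support 104
deletion       chrI:182265-182614  size 102 bp  support 25
```

— the planted 100-bp deletion recovered as a long-span cluster with a
102-bp estimate, and the contracted repeat array flagged by the
differing-sizes + coverage-deficit signature — and the TE insertion calls

```
Tc1  chrI:97838   CAACAATTTG[TA]ACGGCTGTTT  support 28+22  TA-confirmed
Tc1  chrI:152884  CGAGAAAGGA[TA]CTGCGAATCA  support 26+33  TA-confirmed
Tc2  chrI:109214  TGTTCCGCAA[TA]CATCAAATTT  support 22+26  TA-confirmed
```

each at the exact planted TA position (1-based position of the T), with the
10-bp flanks on either side of the duplicated TA and forward/reverse
supporting read counts.

A command-line interface wraps the same stages:

```
rec-reseq all --config config.yaml --outdir out/      # simulate→map→call→report
rec-reseq simulate --config config.yaml --outdir out/
rec-reseq map --ref ref.fa --fq1 r1.fq --fq2 r2.fq --max-mm 2 --out aln.sam
rec-reseq call-snv --sam aln.sam --ref ref.fa --out-vcf calls.vcf --out-spectrum spectrum.tsv
rec-reseq call-sv  --sam aln.sam --ref ref.fa --out-bed sv.bed --out-tsv sv.tsv
rec-reseq call-te  --sam aln.sam --ref ref.fa --catalog out/catalog --out-tsv te.tsv --out-bed te.bed
rec-reseq report --outdir out/
```

`all` writes FASTA/FASTQ/SAM/VCF/BED/TSV artifacts, a truth-vs-called
recovery report and a manifest with SHA-256 digests; the same seed
reproduces every output byte-identically.

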