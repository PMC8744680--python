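# Methods

## The problem

Most TSS-mapping protocols (CAGE and relatives) depend on the m7G cap and
therefore see only RNA polymerase II starts. A 5'-end capture chemistry that
first decaps Pol II transcripts (yDcpS), then recaps both the resulting
diphosphate ends and the native triphosphate ends of Pol I / Pol III /
mitochondrial transcripts with a biotinylated GTP analog (vaccinia capping
enzyme), makes *all* primary 5' ends selectable on streptavidin. Sequencing
three matched libraries then identifies and classifies TSSs at
single-nucleotide resolution:

* **ALL** — the enriched library (all primary 5' ends);
* **CT** — an unenriched control taken before the streptavidin step
  (dominated by processed/degraded 5' ends, e.g. mature rRNA);
* **CIP** — an enriched library from phosphatase-pretreated RNA
  (triphosphate ends destroyed, so only capped starts survive enrichment).

This package implements everything downstream of alignment: tag counting,
TSS calling and classification, annotation, benchmarking, and a simulator
that emulates the three libraries so the pipeline is testable without
sequencing data.

## Tag counting and normalisation

A read's 5'-end tag is its 5'-most *aligned* base: `start` for a
plus-strand alignment, `end − 1` for a minus-strand one (0-based half-open
internally; conversion to 1-based display coordinates is centralised in one
helper module). 5' soft clips consume no reference positions, so a clipped
read tags the first aligned base; the clipped sequence is retained because
nontemplated adenosine run-on at the start of transcripts ("stuttering",
seen at mitochondrial promoters) appears exactly there. For minus-strand
reads the stored clip is reference-forward as in the SAM record and is
reverse-complemented when a profile in transcript orientation is requested.

Only primary alignments contribute (secondary/supplementary are excluded as
with `samtools view -F 256`; a keep-secondary flag exists for diagnostics),
and for paired-end input only read 1 carries the original 5' end. Counts
are normalised as tags per million primary mappable reads,

TPM(x) = count(x) / library_size × 10⁶,

where `library_size` defaults to the number of primary mapped reads
streamed and can be overridden to reproduce a down-sampled normalisation.
(Parts of the literature abbreviate the same quantity TRM; this package
uses TPM throughout.) A MAPQ filter removes tags but never shrinks the
denominator: low-MAPQ reads are still mappable reads. Zero-denominator TPM
is an error, never a silent 0/0.

## Calling and classification

Per position key (chrom, position, strand), matched exactly across the
three tables — no windowing, since the method is single-nucleotide:

| step | rule | default |
|---|---|---|
| candidate | TPM_ALL ≥ min_tpm | 1 |
| high-confidence | TPM_ALL / TPM_CT ≥ hc_ratio | 1 |
| non-Pol II | TPM_ALL / TPM_CIP ≥ cip_threshold | 4 |

All thresholds are inclusive. The two ratios define four quadrants:
II = high-confidence ∧ CIP-sensitive (non-Pol II), IV = high-confidence ∧
CIP-resistant (Pol II), I/III = the control-depleted false positives split
by the same CIP ratio. Ratios with a zero denominator are +∞ — a position
absent from the control (or CIP) library is maximally enriched (depleted).
An optional pseudocount (default 0) exposes the damped alternative; it is
off by default because at single-position resolution absent-in-control
genuinely is the strongest possible evidence.

High-confidence filtering precedes polymerase classification; classifying a
false positive is rejected with an error. Classification is invariant under
joint rescaling of the three library sizes (it depends only on TPM ratios)
and monotone: adding CIP-library signal can only move a position toward
Pol II.

Mitochondrial positions attract multi-mapping artifacts from nuclear
paralogs, so a stricter uniqueness filter applies there: keep a position
only if the fraction of its tags with MAPQ strictly above a threshold
(default 3, the STAR convention; 39 for Bowtie 2) is ≥ 0.8.

### Serialization

The browser track is bedGraph with a sign convention — positive values are
Pol II TSSs, negative values non-Pol II, magnitude = enriched-library TPM.
bedGraph has no strand column, so BED6 (name = class, score = TPM) is the
lossless companion; the full record set round-trips through a TSV with all
fields.

## Annotation

A TSS is assigned to a gene when it overlaps one of the gene's exons
(distance 0) or lies at most 200 bp upstream of an exon's first base in
gene orientation (inclusive at exactly 200; the boundary is not specified
more precisely anywhere authoritative, and inclusive matches every other
threshold in the pipeline). Exons wholly upstream of the TSS are never
candidates — a TSS may sit upstream of or within its gene, not past it.
Ties break by annotation input order, reproducing the common
closest-feature tool behaviour (`-t first -D a -iu -s`). Assignment is
computed against all exons, not first exons only, matching that tool usage.

Unassigned TSSs are clustered into loci by single linkage per
(chromosome, strand): consecutive sorted positions at most 20 bp apart
chain together. Strand separation is the package's choice — the convergent
arrangement of Pol III genes makes opposite-strand merging biologically
incoherent — and is configurable via the strand field of the inputs.

Anchor-relative histograms report the strand-oriented signed offset of each
TSS to its nearest same-strand anchor (negative = upstream), used e.g. for
TSS positions around mature tRNA 5' ends. Equidistant ties resolve to the
upstream offset. Base-composition profiles read strand-oriented flanking
sequence (reverse-complemented for minus TSSs) and label the TSS base +1
with no offset 0, the initiator-motif convention; the −1[C/T] +1[A/G]
summary fractions are reported alongside the per-offset matrix.

## Benchmarking

Precision = 100 × TP/(TP+FP) with TP = high-confidence Pol II TSSs
overlapping a reference: position sets are matched within ±window
(window 1 for CAGE, 0 for annotation starts; strand-aware), peak intervals
by point-in-interval. Sensitivity = TP/(TP+FN) where FN are reference TSSs
that are expressed (FPKM ≥ cutoff — the cutoff is a parameter because it is
conventionally swept), peak-supported, and undetected. References without
an FPKM entry are excluded and counted. Zero-denominator metrics propagate
as NaN, never 0.

Transcript-body coverage maps per-base tag counts (or read pile-up, in
reads mode) onto 100 percentile bins 5'→3': bin = ⌊rank × 100 / length⌋,
ties to the lower bin. The exact binning convention is otherwise arbitrary,
so it is fixed here and covered by a conservation invariant (row sums equal
the transcript's kept tag total). Transcripts ≤ 300 bp are excluded; in
tags mode so are transcripts with fewer than library_size/10⁶ total tags,
in reads mode those with FPKM < 10. A 5'-end library should concentrate in
bin 1; RNA-seq should be flat.

qPCR recovery = 100 × 2^−(mean Cq_input − mean Cq_enriched), strictly
decreasing in the Cq difference. Applied to published duplicate two-decimal
Cq values the formula gives 31.9% where 32.10% was reported from the same
experiment — the discrepancy is Cq rounding in the inputs (unrounded
instrument Cqs evidently fed the original calculation); the formula, not
the printed rounding, is normative here.

## The simulator

`simulate` builds a seeded uniform-random genome (default two 100 kb
contigs), places non-overlapping transcription units on both strands
(lengths uniform in 400–1200 bp, lognormal(0, 1) abundances), and draws
already-aligned reads for the three libraries. Emitting aligned SAM rather
than FASTQ keeps the test surface aligner-free; the pipeline's scope starts
downstream of alignment anyway.

Four 5'-end chemistries with a capture-probability matrix per library:

| end class | ALL | CIP | CT | expected outcome |
|---|---|---|---|---|
| capped (m7G, Pol II) | 1 | 1 | 1 | Pol II |
| ppp (triphosphate, non-Pol II) | 1 | ε | 1 | non-Pol II |
| methyl_ppp (γ-methyl-triphosphate, 7SK-like) | 1 | 1 | 1 | Pol II |
| processed (mono-P/degraded) | ε | ε | 1 | never high-confidence |

ε defaults to 0.01: no quantitative capture efficiencies are published for
the chemistry, so 1-vs-1% is an engineering choice (qualitatively matching
the reported qPCR depletions) exposed in the config, and deliberately > 0
so the ratio filter — not mere presence/absence — is exercised. The
methyl_ppp truth is *Pol II*, on purpose: γ-methyl-triphosphate ends are
phosphatase-resistant, so the method misassigns them, and the truth table
documents the caveat instead of idealising it.

Defaults: 50 units (20 capped / 15 ppp / 5 methyl_ppp / 10 processed),
200,000 reads per library, read length 50, degraded_fraction 0.3 (a
degraded read starts at a uniform internal transcript position with a
processed end regardless of its gene's chemistry — degradation dominates
real total-RNA preparations, which is what the unenriched control exists to
flag), positional jitter 0 (a ±1 start-offset mass is available to emulate
imprecise initiation but is off by default so truth matching stays exact).
All randomness flows from one seed through named substreams; every artifact
is a pure function of the config.

### What passing the end-to-end checks does and does not show

The noise-free regime (ε = 0, no degradation, no jitter, 10⁵ reads) must
recover the truth exactly; this validates the pipeline's logic, not its
robustness. The stress regime (the defaults: ε = 0.01, 30% degradation,
2 × 10⁵ reads per library) still classifies all 50 true TSSs correctly, but
degraded reads create background candidate positions of which only ~60% are
removed by the control filter. The survivors are positions whose exact
control coverage happened to be zero, making the enrichment ratio +∞ — a
real behaviour of the per-position filter at desk-scale depth, where a
single read already clears TPM ≥ 1 (at 2 × 10⁵ reads, TPM 1 ≡ 0.2 reads;
at the published 63 million-read depth the same threshold demands 63
reads, which suppresses this failure mode). The simulator also omits
sequencing error, PCR duplication, mapping ambiguity beyond a MAPQ flag,
and any realistic promoter sequence composition, so passing these checks
says nothing about alignment artifacts or motif-level results on real data.

## Numerical choices

* Ratios: +∞ on zero denominators (NaN only for 0/0, which cannot reach
  the candidate stage); comparisons against thresholds are plain `>=`.
* Tag counting is a pure tally — order-independent by construction.
* Down-sampling uses `random.Random(seed).sample` (uniform, without
  replacement) and preserves read order.
* Percentile binning: `floor(rank * 100 / length)`, conserving totals.
* Problem sizes in the test suite and acceptance runs (10⁵–2 × 10⁵ reads
  per library, 50 transcription units, 100 kb contigs) are chosen so a full
  pipeline run completes in seconds while every per-class outcome is backed
  by thousands of reads.

## Known limitations

* Candidate calling thresholds the merged enriched library only; per
  -replicate thresholding is not implemented (merging precedes calling).
* Multimapping reads contribute a tag at their primary position (the
  aligner's choice); only the mitochondrial uniqueness filter interrogates
  MAPQ beyond the global cutoff.
* No CAGE-style tag clustering into peaks: the method is per-nucleotide,
  and locus clustering applies only to unannotated TSSs.
* bedGraph output is inherently strandless; use BED6 where strand matters.
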