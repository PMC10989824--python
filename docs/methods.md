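# Methods

This note documents the models and procedures implemented in
`erv-activity`, the defaults and why they were chosen, what the synthetic
data emulate (and do not), and the numerical conventions used throughout.

## Coordinates and formats

All intervals are 0-based half-open internally; conversions happen only at
parse/write boundaries (RepeatMasker `.out` and GTF are 1-based inclusive,
BED is 0-based half-open).  RepeatMasker's complement strand marker `C` is
mapped to `-`.  Rows whose class/family field is not LTR-type
(SINE/LINE/DNA/Simple_repeat/...) are skipped and counted.  Overlapping or
nested repeat rows are kept as distinct loci: the analysis counts
elements, not merged intervals.  Rows flagged by RepeatMasker as
overlapped by a higher-scoring match are kept, matching its default
reporting.

ERV class assignment is longest-token matching with explicit precedence
(`ERVL-MaLR` before `ERVL`, then `ERVK`, `ERV1`); any other LTR-type
string becomes `other-LTR`, which is carried internally but excluded from
the four-class summary tables by default.

## Gene model and genomic context

The *refined exon set* of a gene is the union of exons over all its
annotated transcripts, merged after sorting; introns are the complement of
that union within the gene span (min exon start to max exon end).  This
union refinement replaces splice-graph-based exon estimation: it requires
nothing beyond the GTF and is exact for the question asked here (does an
ERV locus overlap exonic sequence of any isoform).

Each chromosome is partitioned by gene-span coverage depth:
intergenic (0 spans), intragenic (exactly 1), *overlapped* (≥ 2).  The
"overlapped gene region" is thus defined as genomic positions covered by
two or more distinct gene spans; the generator's `overlapped` loci are
planted inside such regions.  A locus's level-1 label is the category
holding the majority of its bases, ties broken overlapped > intragenic >
intergenic — a deterministic rule chosen because boundary-straddling loci
need *some* fixed convention.  Intragenic loci get a level-2 label:
`exon` when the genic part lies entirely in the exon union, `intron` when
it avoids it entirely, `others` when it crosses an exon boundary.  Strand
is ignored for context: an ERV inside a gene on either strand is
intragenic.  The host gene of a locus is the gene with the largest span
overlap, ties broken lexicographically by gene id.

## Quantification

Union-mode counting follows htseq-count semantics on one feature set at a
time: a fragment (paired mates pooled) contributes to a feature only when
its aligned blocks overlap exactly one feature; multi-feature overlaps are
discarded as `ambiguous` and non-overlaps as `no_feature`; unmapped,
secondary and supplementary records are skipped.  Genes and ERV loci are
counted in separate passes, so a read in an intronic ERV can count toward
both the locus and (if exon-overlapping) the gene.  Counting is unstranded
by default — library strandedness is data-dependent and exposed as a flag.
TPM denominators are computed within each feature set, consistent with the
separate passes.  Gene lengths for TPM are exon-union lengths; ERV lengths
are locus lengths.

PCA operates on log2(TPM+1), centered but not scaled, via SVD; the
largest-magnitude loading of each component is made positive so
coordinates are deterministic.  Zero-variance features are retained (they
contribute nothing).

## Activity and partition

"Active in tissue t" defaults to ≥ 1 read in ≥ 1 replicate of t — activity
is defined as presence of transcripts, so the laxest rule is the
definitional one; stricter `min_count`/`min_replicates` are configuration.
The partition label (core / exclusive:tissue / shared:subset / inactive)
is a pure function of the per-tissue activity set.  Percentages are
*truncated* toward zero at one decimal (floor(1000 n/d)/10), the
convention that reproduces all published summary percentages
simultaneously.

## Differential expression

A deliberately small NB Wald pipeline stands in for a full DESeq2-style
analysis (no Cox-Reid adjusted likelihood, no MAP fold-change shrinkage,
no independent filtering), because every downstream claim rests on
thresholded calls (FDR < 0.05, fold change > 2, read as |log2FC| > 1):

* size factors: median of ratios to the geometric-mean reference over
  features nonzero in all samples (pseudo-reference fallback for sparse
  matrices);
* dispersion: per-locus method of moments on normalized counts, variance
  pooled within condition, α = max(0, (s² − μ̄)/μ̄²), then shrunk 50/50
  toward a least-squares trend α(μ) = a0 + a1/μ and floored below by the
  trend itself.  The trend floor is this package's own choice: with three
  replicates the raw moment estimate frequently collapses to zero, and
  letting it undercut the mean-dispersion relation makes the Wald test
  anti-conservative (empirically ~0.065 type-I at nominal 0.05; with the
  floor, 0.037-0.050 across null simulations);
* test: log2FC = log2((m̄_A + ½)/(m̄_B + ½)) on normalized group means
  (pseudocount ½ keeps zeros finite), SE from the delta method with group
  mean variance (1/n²) Σ_j (μ̂/s_j + α μ̂²), p = 2(1 − Φ(|log2FC|/SE)),
  BH-adjusted within the contrast.  All-zero loci are excluded from
  testing and reported as NaN.

Tissue-specific transcription: a locus is `up-in:t` only when
significantly up in t against *every* other tissue (this makes exclusive
per-tissue counts well defined); loci up in exactly two tissues against
the third are `up-in-two`; the rest are `constant`.  By default the calls
run on the core-active locus set (tissue-specific *activity* is already
captured by the partition); `locus_set: all` runs them on all active loci.

## Correlation with host genes

Each point is one (locus, host gene) pair within one tissue: x and y are
replicate-mean log2(TPM+1) of the gene and the locus.  With only three
replicates per tissue, per-pair across-sample correlation would be
unstable, so pooling across pairs (one R per context category per tissue)
is the supported mode.  Pairs require the locus to be active in the tissue
and to have a host gene; intergenic loci are excluded (no assignable
target gene), and intragenic `others` loci fit none of the three reported
categories (exon / intron / overlapped) and are excluded as well.
Zero-variance or < 3-pair categories report an undefined R with the
reason.

## env screen

Loci are translated in all six frames (stops as `*`, N-containing codons
as `X`) and aligned locally against a genus-labelled env protein panel
with BLOSUM62 and BLAST-style affine gaps (open 11, extend 1, i.e. a gap
of length k costs 11 + k); `*` scores −4 against everything.  Thresholds
are a raw score ≥ 60 and ≥ 30 aligned residues, exposed as configuration —
raw-score thresholds were preferred over E-values because Karlin-Altschul
calibration adds machinery without changing any thresholded decision here;
the null false-positive rate is bounded empirically in the tests.  A
shared 5-amino-acid word prefilter (in the spirit of BLAST seeding) skips
frame/query pairs with no exact seed; survivors get the exact
Smith-Waterman optimum, so the filter only skips pairs that could not have
produced a reportable hit in practice.  When several queries hit one
locus, the hit with the greatest aligned length assigns the genus (ties:
higher score, then query id).  SU-domain coverage counts aligned query
residues inside the panel's SU span; loci covering more than 70 residues
(strict) are flagged.  The panel format is plain FASTA with
`genus=`/`su_span=` header tags, so any user-supplied set of
representative env proteins can be used.

## Synthetic data

The generator emulates the target study design: 2 chromosomes x 1 Mb, 200
genes (2-3 exons of 400-800 bp, introns 1500-3500 bp, 60% of genes with a
second transcript that skips an exon or extends one, so exon-union
refinement is exercised), overlapping gene pairs (floor(n·f/2) pairs with
500-1200 bp span overlap), 2,000 ERV loci allocated by largest remainder
over the context mix (71.4% intergenic, 27% intron, remainder exon /
others / overlapped) and the class mix (46.8 / 29.9 / 15.1 / 8.2% for
ERVL-MaLR / ERVL / ERV1 / ERVK), 3 tissues x 3 replicates, 44% active
loci of which 38.1% are tissue-specific, and a 1M-read library per sample.
Contexts are planted against the generator's own gene model; the test
suite independently re-derives every label with a per-base brute-force
oracle.

Counts are negative binomial with Var = μ + αμ² and a single shared
α = 0.1.  Inactive loci have expected count exactly zero — the
active/inactive dichotomy is presence of transcripts, not a low/high
threshold.  Gene log2-means are N(5, 2) with N(0, 0.25) tissue effects; a
locus with host gene g and context c has log2 μ = coupling(c)·log2 μ_g +
N(3, 1), with default couplings 0.9 (overlapped), 0.6 (intron), 0.3
(exon/others), 0 (intergenic) — this induces the context gradient of
locus-gene correlation, and `analytic_population_r` gives the implied
population R (treating realized log2 feature-length variances as part of
the design; NB measurement noise is neglected, which is accurate at the
default means).  Per-sample totals are scaled exactly to
library_size x U(0.95, 1.05); the per-sample scalar is global and is
absorbed by size-factor normalization downstream.  A fraction of core
loci (15%) carries a planted log2FC of 2 in one tissue, providing the
power/recall targets for the Wald test.

Fields beyond the basic design — `n_env_loci` (24), `frac_shared_pair`
(15% of active loci active in exactly two tissues), and
`frac_core_upregulated` (15%) — exist so that every Venn region and
differential-expression label class is populated; values were fixed once
at what a small multi-tissue study would plausibly show.

env loci embed a reverse-translated window of a known panel query
(random synonymous codons), mutated at the configured nucleotide
substitution rate and inserted at a random frame and strand into random
background sequence.  Note that a nucleotide rate of 0.1 hits ~27% of
codons and yields ~78% amino-acid identity; rates above 0.35 trigger a
warning because hits may fall below the alignment thresholds (which the
tests use to probe the miss path).

Reads are not simulated by default — the downstream claims live at count
level.  A small SAM emitter (uniform single-end placement inside a
feature) exists solely to exercise the union-counting path.

What the generator does *not* emulate: read-level error models, splicing,
multi-mapping (ERV repeats are highly multi-mapping in real data and this
pipeline, like the union-counting approach it follows, does not rescue
multi-mappers), sequence realism of LTRs, fragmented multi-row elements
sharing a RepeatMasker ID, and batch effects.  Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
statistics under the stated model, not robustness to those real-data
complications.

## Problem sizes used in the test suite

The default simulation (2,000 loci, 9 samples) drives most planted-truth
tests; the context-classification oracle runs at 10,000 loci; null
calibration uses 2,000-locus two-group simulations over 10 seeds; the
correlation gradient uses 1,200 loci (600 pairs per context) over 5
seeds; alignment oracles use 50 random peptide pairs up to 30 aa.  The
full suite runs in well under a minute on one CPU.

## Determinism

Every generator stage derives its RNG from (seed, stage index); identical
configurations produce byte-identical output files.  The pipeline report
records SHA-256 checksums of all stage inputs and outputs, and reruns skip
stages whose inputs are unchanged; a checksum mismatch triggers
recomputation.
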