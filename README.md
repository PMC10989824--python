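# erv-activity

Genome-wide analysis of endogenous retrovirus (ERV) transcription from
RepeatMasker annotations and multi-tissue RNA-seq.

Mammalian genomes carry hundreds of thousands of ERV loci — mostly solo
LTRs and fragmented ("slimmed down") proviruses of the ERV1, ERVK, ERVL
and ERVL-MaLR classes.  Most are silent, but a sizeable fraction produces
transcripts, sometimes coupled to the expression of the host gene they sit
in, and a subset still encodes fragments of the envelope (*env*) protein
whose surface (SU) domain can interfere with retroviral receptors.  This
package turns that analysis into a tested, reusable pipeline for anyone
with a RepeatMasker `.out` file, a GTF gene annotation and per-tissue
count matrices (or SAM alignments):

1. **Catalog** — parse RepeatMasker output into an ERV locus catalog with
   class assignment (`ERVL-MaLR` before `ERVL` precedence) and
   per-chromosome class x context summary tables.
2. **Genomic context** — build a gene model from the GTF (exon unions over
   all transcripts, introns as their complement) and classify each locus
   at two levels: intergenic / intragenic / overlapped (covered by two or
   more gene spans), and within genes exon / intron / others
   (exon-boundary-crossing), by majority base pair with fixed tie-breaks.
3. **Quantification** — union-mode read counting (htseq-count semantics)
   and TPM conversion, TPM_i = 10^6 (c_i/l_i) / Σ_j (c_j/l_j), plus a PCA
   report of samples on log2(TPM+1).
4. **Activity** — a locus is *active* in a tissue when it has ≥ 1 read in
   ≥ 1 replicate (configurable); active loci are partitioned into *core*
   (all tissues), *tissue-specific* (exactly one) and shared sets, with
   Venn summaries and truncated percentages.
5. **Differential expression** — a from-scratch negative-binomial Wald
   test (median-of-ratios size factors, method-of-moments dispersions
   shrunk toward an α(μ) = a0 + a1/μ trend, delta-method standard errors,
   Benjamini-Hochberg FDR), thresholded at FDR < 0.05 and fold change > 2;
   a locus is "upregulated in tissue t" only if significant against every
   other tissue.
6. **Correlation** — Pearson R between replicate-mean log2(TPM+1) of
   active loci and their majority-overlap host genes, stratified by
   exon / intron / overlapped context.
7. **env screen** — six-frame translation plus Smith-Waterman alignment
   (BLOSUM62, BLAST-style 11/1 affine gaps) against a genus-labelled env
   protein panel; the longest hit assigns the retroviral genus, and
   aligned SU-domain residues are counted (flagged when > 70).

A synthetic-data generator produces every input with planted ground truth
(contexts, activity sets, fold changes, gene-ERV coupling, env ORFs with
known genus), so the whole pipeline is testable without downloads.

## Worked example

Generate a synthetic study (2 chromosomes x 1 Mb, 200 genes, 2,000 ERV
loci, 3 tissues x 3 replicates, 44% active loci) and run the pipeline:

```sh
erv-activity simulate --seed 7 --outdir data
# wrote 2000 loci, 200 genes, 24 env loci to data

cat > run.yaml <<EOF
rm_out: data/repeats.out
gtf: data/annotation.gtf
gene_counts_prefix: data/genes
erv_counts_prefix: data/ervs
loci_fasta: data/loci.fasta
env_panel: data/env_panel.fasta
outdir: out
EOF
erv-activity run --config run.yaml
```

The run report (abridged) prints:

```json
{
  "catalog":  {"loci": 2000, "skipped_rows": 40},
  "context":  {"assigned": 2000, "by_context": {"intergenic": 1428,
               "intron": 540, "exon": 12, "others": 12, "overlapped": 8}},
  "activity": {"active_union": 880, "core": 413,
               "per_tissue": {"lung": 613, "trachea": 613, "amygdala": 612}},
  "diffexpr": {"tested": 413, "upregulated_per_tissue":
               {"lung": 19, "trachea": 21, "amygdala": 18}},
  "env":      {"env_loci": 24, "active_env": 11}
}
```

Reading the numbers: 2,000 RepeatMasker rows became loci and 40 non-LTR
decoy rows were skipped; 71.4% of loci are intergenic; 880 of 2,000 loci
(44%) are active somewhere; 413 (46.9% of active, printed in
`out/venn.json`) are core-active in all three tissues; of the core set, 58
loci are significantly upregulated in exactly one tissue; 11 of 24 env
loci are transcribed.  `out/correlation.tsv` holds the context-stratified
locus-host-gene correlations, e.g. for amygdala intronic loci R = 0.61
(p = 2.3e-17, n = 159 pairs), with overlapped loci showing the strongest
coupling — the gradient planted by the generator.

All stages are also available as subcommands (`erv-activity catalog`,
`context`, `quantify`, `pca`, `activity`, `de`, `correlate`, `env`) for
running on real data; reruns reuse cached stage outputs keyed by input
checksums.

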