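# Methods

## Background and scope

The class I HLA genes (HLA-A, -B, -C) present tumor peptides to CD8 T
cells, and tumors escape this surveillance by disabling individual HLA
alleles. Four routes matter: somatic mutation of an allele, loss of
heterozygosity (LOH), allele-specific transcriptional repression, and
allele-specific alternative splicing. `hladisrupt` detects all four from
whole-exome and RNA-seq alignments of tumor, germline and tumor-adjacent
normal samples, working throughout against a patient-specific reference
built from the patient's six typed alleles. Upstream steps — short-read
alignment, HLA typing, somatic variant calling, VEP annotation,
peptide-HLA binding prediction, purity/ploidy estimation — are consumed as
inputs, not re-implemented.

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted on read.

## Patient-specific reference

The allele database is a FASTA of genomic allele sequences plus a TSV of
exon/intron features (a stable interchange format standing in for the
IMGT/HLA flat files). Features must tile each allele without gaps, with
exons and introns alternating; violations are hard errors naming the
offending allele or interval. A gene typed with two identical allele names
is homozygous: it is excluded from allele-specific analyses (there are no
allele-distinguishing SNPs) but retained for gene-level outputs.

Candidate HLA reads are "fished" from the input alignment because HLA
reads frequently fail to map to a generic genome: a read pair is kept if
either mate is unmapped, maps to chromosome 6 or an alternate contig, or
contains an exact 30-mer from the reference k-mer index. K-mers are
indexed on both strands since reads are unstranded. After external
re-alignment to the patient reference, per-allele alignments are filtered:
reads with more than one substitution (edit distance minus indel bases)
are removed, and any indel-bearing read is removed outright — an indel
against the patient's own allele indicates the read belongs to the other
allele or is erroneous.

## Allele SNPs and DNA analysis

All allelic quantification rests on the substitution columns of the global
pairwise alignment of a gene's two allele sequences (Biopython
`PairwiseAligner`, match 2 / mismatch −1 / gap open −6 / extend −0.5; gap
columns never yield SNPs). SNPs whose summed germline depth falls below
`min_depth` (default 30; 5 is appropriate for shallower cohorts) are
dropped for all of the patient's samples, keeping tumor and germline SNP
sets identical.

Copy number uses the standard two-component purity/ploidy mixture. With
purity ρ, tumor ploidy ψ and allele copy number n, the library-size-
normalised tumor/germline depth ratio at a SNP is

    r = 2(ρn + (1 − ρ)) / (ρψ + 2(1 − ρ)),

inverted per SNP to n = (r(ρψ + 2(1 − ρ))/2 − (1 − ρ))/ρ. The gene's
estimate is the mean of per-SNP values with a two-sided 95% t interval;
negative per-SNP values are retained before averaging (they carry
sampling-noise information) and the reported mean is floored at zero.
SNPs with zero germline depth are excluded from the ratio.

DNA allelic imbalance (AIB) is a two-sided paired Wilcoxon signed-rank
test on per-SNP allele depths (exact null for < 25 informative pairs,
normal approximation otherwise; all-tied input returns p = 1). LOH is
called for an allele when its copy number is below 0.5 with AIB p < 0.01;
both alleles below 0.5 is a biallelic loss, which supersedes LOH. The
expected depth — mean tumor depth scaled by ρn/(ρn + (1 − ρ)), the
fraction of DNA copies contributed by cancer cells — must reach 10 for
both alleles; together with ≥ 10 SNPs and a CI width < 2.5 this defines
DNA evaluability. The CI threshold is applied to the full interval width.

Somatic mutations are damaging when the VEP consequence includes
stop_gained, frameshift_variant, start_lost or stop_lost, the call is
PASS, at least ten reads support the alternate allele, and the gene passes
the DNA filters.

## RNA analysis

Allelic expression is RPKM over the allele's exonic length with the
library size (paired aligned reads) as denominator. HLA allelic
expression varies widely between individuals and between a person's own
two alleles even in normal tissue, so repression is only ever measured
against the patient-matched tumor-adjacent normal — never a cohort
average. Per allele, tumor and normal library-size-normalised SNP depths
are compared with a one-sided paired Wilcoxon test; the two per-gene
p-values are BH-adjusted and an allele is repressed when adjusted p < 0.01
with a tumor/normal expression ratio below 1. Repression of an allele that
also carries LOH or a damaging mutation is flagged as genomically
explained. RNA evaluability requires DNA evaluability, ≥ 10 exonic SNPs,
≤ 50% of the gene's reads tied between its two alleles and ≤ 5% hitting
multiple HLA genes. Reads tied between a gene's two alleles are split
equally for gene-level totals and excluded from allele-level totals.

## Alternative splicing

Junctions are the N-gap intervals of spliced CIGARs, counted over uniquely
mapping reads (primary, NH = 1). Classification against the allele's
annotation: an interval equal to an intron is canonical; donor-to-acceptor
intervals containing whole exons are complete exon skips; exactly one
annotated boundary with the other strictly inside an exon (intron) is a
partial exon skip (partial intron retention). Junctions overlapping the
first or last exon are excluded; everything else is unclassified. Complete
intron retention produces no junction and is instead detected from
unspliced reads crossing both intron boundaries by ≥ 10 bases with no
zero-coverage intronic base.

The novel transcript proportion is p = novel/(novel + canonical support),
where canonical support is the mean unique-read count of the canonical
junctions overlapping the novel interval — one junction for partial
events, two for a complete exon skip. Averaging the two flanking
junctions avoids double-counting the same canonical transcript pool.

Consequences come from rebuilding the mature transcript with the event
applied: inframe iff the coding-length change is a multiple of 3; a
premature termination codon (PTC) is flagged when translation of the
modified transcript stops strictly before the canonical stop codon's
mapped position; removing the start codon reports start_lost.

Tumor enrichment uses a two-sided Fisher's exact test on the
(novel, canonical) × (tumor, normal) read table, BH-adjusted at 0.05,
with direction from the proportions. For tumor-enriched events the
proportion is divided by tumor purity (capped at 1) to estimate the
proportion within cancer cells. Patient-level evidence filters follow two
modes: in normal-tissue cohorts a junction needs ≥ 2 reads in the focal
sample and ≥ 20 in another sample of the same individual; in tumor
cohorts it must be tumor-enriched/depleted and reach ≥ 20 reads in at
least one of the patient's samples.

## Summaries

Per region, intact alleles (of six) are counted under three accounting
modes: none; subtracting genomically lost alleles (LOH, biallelic loss or
damaging mutation); and additionally subtracting repressed alleles. An
allele disrupted by several mechanisms counts once, so the triple is
always non-increasing. Tumor-enriched splicing is reported but never
subtracted from the intact count. The effective neoantigen burden counts
mutations with at least one peptide at eluted-ligand rank ≤ 0.5 (inclusive)
against at least one intact allele. A disruption event is ubiquitous if
present in every evaluable primary region (≥ 2 regions required),
heterogeneous otherwise; an allele shows convergent disruption when two
different mechanisms hit it in entirely separate regions (disjoint region
sets). The Danaher CD8 score is the mean log2 TPM of CD8A and CD8B with a
0.01 pseudocount so zero TPMs stay finite.

## Synthetic data and what it does (not) show

The simulators define the conditions under which the statistical
guarantees are tested:

- **Toy allele DB** — 3 genes × 4 alleles, 4 exons of 99 bp (a codon
  multiple, so the frame closes without UTRs) and 100 bp GT…AG introns;
  alleles differ from a per-gene base sequence only by substitutions at
  rate 0.02/bp, placed so every allele's CDS stays translatable.
- **DNA depths** — germline allele depths Poisson(mean_depth/2 = 30);
  tumor depths Poisson under the mixture ratio; 20 SNPs at 60× emulate
  exome depth over an HLA gene.
- **RNA depths** — Poisson(50) per allele over 10 exonic SNPs, with a
  per-allele knockdown factor for repression experiments.
- **Spliced reads** — error-free 100 bp reads with exact M/N CIGARs, drawn
  from the canonical vs modified transcript with length-weighted
  probability (abundance × number of fragment start positions). The
  length weighting reproduces uniform fragmentation, under which
  junction-spanning counts are proportional to abundance alone — the
  property that makes the novel transcript proportion unbiased. An
  equal-weight draw would overweight the shorter (skipped) transcript's
  junctions.
- **Neoantigen tables** — per (mutation, allele) binding with a fixed
  probability; binders get a best rank in [0, 0.5].

Real data differ in ways the simulators deliberately omit: sequencing
error and mapping ambiguity between near-identical alleles, overdispersed
(non-Poisson) depth, GC and positional coverage bias, fragment-length
variation, incomplete annotation, and tumor subclonality beyond a single
purity parameter. Passing the simulation-based checks therefore
demonstrates correctness of the estimators and callers under their own
model assumptions, not end-to-end accuracy on patient cohorts.

## Numerical choices

- Wilcoxon: exact distribution below 25 informative pairs, else normal
  approximation; zero differences dropped; all-tied input → p = 1.
- t interval: undefined (NaN) below 2 SNPs; degenerate (zero-width) when
  all per-SNP estimates coincide.
- Fisher tables round the (possibly fractional) mean canonical support to
  the nearest integer; an all-zero table returns p = 1.
- Problem sizes in the test and acceptance suites (200 replicates per
  copy-number condition, 1,000 AIB null simulations, 200× splice depth,
  exhaustive ~245,000 junction classifications) keep the full run under a
  minute on one CPU while leaving Monte-Carlo error well inside the
  asserted margins.

## Known limitations

- Realignment of fished reads is delegated to an external aligner; the
  package defines only the pre/post filters.
- The repression and AIB statistics are parameterised choices (Wilcoxon +
  BH at 0.01); other reasonable statistics exist and can be swapped in via
  the exposed parameters.
- Partial splice events are not required to carry canonical GT/AG
  dinucleotides at the novel site; the classification is purely
  positional.
- Homozygous genes have no allele-distinguishing SNPs and are excluded
  from all allele-specific calls.
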