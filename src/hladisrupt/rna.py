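"""RNA-level allele-specific analysis: allelic expression (RPKM), RNA
allelic imbalance, and tumor-versus-matched-normal repression calls.

HLA allelic expression varies widely between individuals and between a
person's own alleles even in normal tissue, so repression in a tumor is
always measured against the same allele in the patient-matched
tumor-adjacent normal sample, never against a cohort average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import bh_adjust, wilcoxon_paired
from .dna import SnpDepthTable
from .reads import AlleleAlignmentStats

MIN_EXONIC_SNPS = 10
MAX_FRACTION_BOTH_ALLELES = 0.5
MAX_FRACTION_MULTI_GENE = 0.05
AIB_ALPHA = 0.01
REPRESSION_ALPHA = 0.01


@dataclass
class AllelicExpression:
    allele: str
    read_count: int
    exonic_length: int
    library_size: int
    rpkm: float


@dataclass
class AibResult:
    gene: str
    sample_id: str
    aib_ratio: float  # major/minor allelic expression, >= 1
    pvalue: float
    adjusted_pvalue: float
    significant: bool
    major_allele: str


@dataclass
class RepressionResult:
    allele: str
    tumor_region: str
    tn_ratio: float  # tumor/normal normalised allelic expression
    pvalue: float
    adjusted_pvalue: float
    repressed: bool
    explained_by_genomics: bool = False


def allele_rpkm(read_count: int, exonic_length: int, library_size: int) -> float:
    """Reads per kilobase of exonic sequence per million library reads."""
    if exonic_length <= 0:
        raise ValueError("exonic length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return read_count * 1e9 / (library_size * exonic_length)


def allelic_expression(
    allele: str, read_count: int, exonic_length: int, library_size: int
) -> AllelicExpression:
    return AllelicExpression(
        allele=allele,
        read_count=read_count,
        exonic_length=exonic_length,
        library_size=library_size,
        rpkm=allele_rpkm(read_count, exonic_length, library_size),
    )


def rna_aib(
    exonic: SnpDepthTable,
    gene: str,
    min_snps: int = MIN_EXONIC_SNPS,
    alpha: float = AIB_ALPHA,
    adjusted_pvalue: float | None = None,
) -> AibResult:
    """RNA allelic imbalance from exonic SNP depths of one sample.

    Paired Wilcoxon signed-rank across per-SNP (allele1, allele2) depths.
    The AIB ratio is the major/minor total-depth ratio (>= 1).  Significance
    is judged on the BH-adjusted p-value when one is supplied (adjustment is
    done across a patient's gene x sample tests); otherwise on the raw p.
    """
    if exonic.n_snps < min_snps:
        raise ValueError(
            f"gene {gene}: {exonic.n_snps} exonic SNPs < required {min_snps}"
        )
    d1 = exonic.df.depth_allele1.to_numpy(dtype=float)
    d2 = exonic.df.depth_allele2.to_numpy(dtype=float)
    p = wilcoxon_paired(d1, d2, alternative="two-sided")
    t1, t2 = d1.sum(), d2.sum()
    major = "allele1" if t1 >= t2 else "allele2"
    hi, lo = max(t1, t2), min(t1, t2)
    ratio = float("inf") if lo == 0 else hi / lo
    adj = p if adjusted_pvalue is None else adjusted_pvalue
    return AibResult(
        gene=gene,
        sample_id=exonic.sample_id,
        aib_ratio=ratio,
        pvalue=p,
        adjusted_pvalue=adj,
        significant=adj < alpha,
        major_allele=major,
    )


def repression_test(
    tumor_exonic: SnpDepthTable,
    normal_exonic: SnpDepthTable,
    alpha: float = REPRESSION_ALPHA,
    loh_or_mutant: tuple[bool, bool] = (False, False),
    allele_names: tuple[str, str] = ("allele1", "allele2"),
) -> tuple[RepressionResult, RepressionResult]:
    """Allele-level transcriptional repression, tumor vs matched normal.

    Per SNP the allelic depth is normalised by library size; a one-sided
    paired Wilcoxon signed-rank tests whether the tumor's normalised depths
    are lower than the normal's for each allele.  The two per-gene p-values
    are BH-adjusted together; an allele is repressed when its adjusted p is
    below ``alpha`` and its tumor/normal expression ratio is below 1.
    ``loh_or_mutant`` marks alleles whose repression is explained by a
    genomic event (LOH or damaging mutation) in the same region.
    """
    merged = tumor_exonic.df.merge(
        normal_exonic.df, on="snp_id", suffixes=("_t", "_n"), validate="one_to_one"
    )
    if len(merged) == 0:
        raise ValueError("tumor and normal share no SNPs")
    pvals: list[float] = []
    ratios: list[float] = []
    for i in (1, 2):
        dt = merged[f"depth_allele{i}_t"].to_numpy(dtype=float) / tumor_exonic.library_size
        dn = merged[f"depth_allele{i}_n"].to_numpy(dtype=float) / normal_exonic.library_size
        pvals.append(wilcoxon_paired(dt, dn, alternative="less"))
        ratios.append(float("inf") if dn.sum() == 0 else dt.sum() / dn.sum())
    adj = bh_adjust(pvals)
    out = []
    for i in (0, 1):
        repressed = adj[i] < alpha and ratios[i] < 1
        out.append(
            RepressionResult(
                allele=allele_names[i],
                tumor_region=tumor_exonic.sample_id,
                tn_ratio=ratios[i],
                pvalue=pvals[i],
                adjusted_pvalue=float(adj[i]),
                repressed=repressed,
                explained_by_genomics=repressed and loh_or_mutant[i],
            )
        )
    return out[0], out[1]


def rna_gene_filters(
    n_exonic_snps: int,
    stats: AlleleAlignmentStats,
    dna_evaluable: bool,
    min_snps: int = MIN_EXONIC_SNPS,
    max_both: float = MAX_FRACTION_BOTH_ALLELES,
    max_multi: float = MAX_FRACTION_MULTI_GENE,
) -> tuple[bool, list[str]]:
    """Gene-level RNA evaluability.

    Requires the DNA filters to pass, at least ten exonic allele SNPs, no
    more than 50% of the gene's reads tied between its two alleles and no
    more than 5% of reads hitting multiple HLA genes.
    """
    reasons: list[str] = []
    if not dna_evaluable:
        reasons.append("dna_filters: gene failed DNA evaluability")
    if n_exonic_snps < min_snps:
        reasons.append(f"min_exonic_snps: {n_exonic_snps} < {min_snps}")
    if stats.fraction_both_alleles > max_both:
        reasons.append(
            f"fraction_both_alleles: {stats.fraction_both_alleles:.3f} > {max_both}"
        )
    if stats.fraction_multi_gene > max_multi:
        reasons.append(
            f"fraction_multi_gene: {stats.fraction_multi_gene:.3f} > {max_multi}"
        )
    return (not reasons, reasons)


def biallelic_repression_discordance(
    tumor_aib: AibResult,
    normal_aib: AibResult,
    both_alleles_repressed: bool,
    genomically_altered: bool = False,
) -> bool | None:
    """Unequal biallelic repression: AIB present in tumor but not normal
    (or vice versa) for a gene with both alleles repressed and no genomic
    alteration.  Returns None when the precondition fails."""
    if not both_alleles_repressed or genomically_altered:
        return None
    return tumor_aib.significant != normal_aib.significant


def split_ambiguous_counts(unique1: int, unique2: int, ambiguous: int) -> tuple[float, float, float]:
    """Gene- and allele-level read counts under the ambiguity rule.

    Reads tied between the two alleles are split equally for the gene-level
    total but excluded from allele-level totals.  Returns
    (allele1_count, allele2_count, gene_count).
    """
    gene_total = unique1 + unique2 + ambiguous
    return float(unique1), float(unique2), float(gene_total)
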