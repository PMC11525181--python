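"""DNA-level allele-specific analysis: allele-distinguishing SNPs, depth
extraction, purity/ploidy-adjusted allelic copy number, DNA allelic
imbalance, LOH and biallelic-loss calls, and damaging-mutation
classification.

The unit of all allelic quantification is the set of positions at which a
patient's two alleles of a gene differ by a substitution ("allele SNPs").
Read depth at those positions, taken from the mismatch-filtered per-allele
alignments, measures each allele separately.

The copy-number model is the standard two-component purity/ploidy mixture:
a tumor sample with purity rho and tumor ploidy psi is a mix of cancer cells
(allele copy number n) and normal cells (copy number 1 per allele).  The
library-size-normalised tumor/germline depth ratio at an allele SNP is then

    r = 2 (rho * n + (1 - rho)) / (rho * psi + 2 (1 - rho))

which inverts to

    n = (r * (rho * psi + 2 (1 - rho)) / 2 - (1 - rho)) / rho.

The per-SNP estimates n_i feed a two-sided t confidence interval; the gene
is evaluable only when that interval is narrow (< 2.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import Align
from scipy import stats

from ._stats import wilcoxon_paired
from .reference import AlleleModel

MIN_SNPS = 10
MIN_EXPECTED_DEPTH = 10.0
MAX_CI_WIDTH = 2.5
DEFAULT_MIN_DEPTH = 30
LOH_CN_THRESHOLD = 0.5
LOH_P_THRESHOLD = 0.01
DAMAGING_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift_variant", "start_lost", "stop_lost"}
)
MIN_ALT_DEPTH = 10


@dataclass(frozen=True)
class AlleleSnp:
    """A substitution distinguishing the two alleles of one gene."""

    gene: str
    pos_allele1: int
    pos_allele2: int
    base1: str
    base2: str
    region: str  # 'exon' | 'intron' | 'utr'

    def __post_init__(self) -> None:
        if self.base1 == self.base2:
            raise ValueError("allele SNP bases must differ")


@dataclass
class SnpDepthTable:
    """Per-SNP allele depths for one sample, with its library size."""

    sample_id: str
    library_size: int
    df: pd.DataFrame  # columns: snp_id, pos_allele1, pos_allele2, region,
    #          depth_allele1, depth_allele2

    COLUMNS = (
        "snp_id",
        "pos_allele1",
        "pos_allele2",
        "region",
        "depth_allele1",
        "depth_allele2",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"SnpDepthTable missing columns: {sorted(missing)}")
        if (self.df[["depth_allele1", "depth_allele2"]] < 0).any().any():
            raise ValueError("negative depths")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def exonic(self) -> "SnpDepthTable":
        return SnpDepthTable(
            self.sample_id, self.library_size, self.df[self.df.region == "exon"].copy()
        )

    def restrict(self, snp_ids: Sequence[int]) -> "SnpDepthTable":
        keep = self.df[self.df.snp_id.isin(set(snp_ids))].copy()
        return SnpDepthTable(self.sample_id, self.library_size, keep)


@dataclass
class SampleMeta:
    sample_id: str
    patient_id: str
    role: str  # 'germline' | 'tumor_region' | 'tumor_adjacent_normal'
    purity: float | None = None
    tumor_ploidy: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("germline", "tumor_region", "tumor_adjacent_normal"):
            raise ValueError(f"unknown sample role {self.role!r}")
        if self.role == "tumor_region":
            if self.purity is None or self.tumor_ploidy is None:
                raise ValueError("tumor samples require purity and ploidy")
            if not 0 < self.purity <= 1:
                raise ValueError(f"purity {self.purity} outside (0, 1]")
            if self.tumor_ploidy <= 0:
                raise ValueError("ploidy must be positive")


@dataclass
class CopyNumberResult:
    allele: str
    n_snps: int
    cn: float  # floored at 0 for reporting
    cn_raw: float  # un-floored mean of per-SNP estimates
    ci_low: float
    ci_high: float
    ci_width: float
    aib_pvalue: float = float("nan")
    expected_depth: float = float("nan")
    loh: bool = False
    biallelic_loss: bool = False
    evaluable: bool = True
    filter_reasons: list[str] = field(default_factory=list)


@dataclass
class MutationCall:
    allele: str
    position: int  # 0-based allele coordinate
    consequences: tuple[str, ...]
    filter_status: str
    alt_depth: int
    damaging: bool


# ---------------------------------------------------------------------------
# Allele SNPs


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -0.5
    return aligner


def find_allele_snps(allele1: AlleleModel, allele2: AlleleModel) -> list[AlleleSnp]:
    """Substitution columns of the global pairwise alignment of two alleles.

    Gap (indel) columns never produce SNPs.  Identical sequences yield an
    empty list, rendering the gene unevaluable for allele-specific work.
    The SNP region (exon/intron) is annotated from allele1's features.
    """
    if allele1.gene != allele2.gene:
        raise ValueError("allele SNPs are defined within one gene")
    s1, s2 = allele1.sequence.upper(), allele2.sequence.upper()
    if s1 == s2:
        return []
    alignment = _make_aligner().align(s1, s2)[0]
    blocks1, blocks2 = alignment.aligned
    snps: list[AlleleSnp] = []
    for (a_start, a_end), (b_start, b_end) in zip(blocks1, blocks2):
        for off in range(a_end - a_start):
            p1, p2 = int(a_start + off), int(b_start + off)
            if s1[p1] != s2[p2]:
                snps.append(
                    AlleleSnp(
                        gene=allele1.gene,
                        pos_allele1=p1,
                        pos_allele2=p2,
                        base1=s1[p1],
                        base2=s2[p2],
                        region=allele1.feature_at(p1).kind,
                    )
                )
    return snps


def snps_to_frame(snps: Sequence[AlleleSnp]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": range(len(snps)),
            "pos_allele1": [s.pos_allele1 for s in snps],
            "pos_allele2": [s.pos_allele2 for s in snps],
            "region": [s.region for s in snps],
        }
    )


def _position_depths(
    alignment_path: str | Path, contig: str, positions: Sequence[int]
) -> list[int]:
    """Aligned-base depth at each position, from a single streaming pass
    (no index needed)."""
    wanted = {int(p): 0 for p in positions}
    mode = "r" if str(alignment_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != contig:
                continue
            for block_start, block_end in read.get_blocks():
                for pos in wanted:
                    if block_start <= pos < block_end:
                        wanted[pos] += 1
    return [wanted[int(p)] for p in positions]


def snp_depths(
    alignment_path_allele1: str | Path,
    alignment_path_allele2: str | Path,
    allele1_name: str,
    allele2_name: str,
    snps: Sequence[AlleleSnp],
    sample_id: str,
    library_size: int,
) -> SnpDepthTable:
    """Depth of the mismatch-filtered per-allele alignments at each SNP."""
    frame = snps_to_frame(snps)
    frame["depth_allele1"] = _position_depths(
        alignment_path_allele1, allele1_name, [s.pos_allele1 for s in snps]
    )
    frame["depth_allele2"] = _position_depths(
        alignment_path_allele2, allele2_name, [s.pos_allele2 for s in snps]
    )
    return SnpDepthTable(sample_id=sample_id, library_size=library_size, df=frame)


def filter_snps_by_germline_depth(
    germline: SnpDepthTable, min_depth: int = DEFAULT_MIN_DEPTH
) -> list[int]:
    """SNP ids whose summed germline depth reaches ``min_depth``.

    Gating on the germline sample keeps the SNP set identical across all of
    a patient's samples.
    """
    total = germline.df.depth_allele1 + germline.df.depth_allele2
    return germline.df.loc[total >= min_depth, "snp_id"].tolist()


# ---------------------------------------------------------------------------
# Copy number


def copy_number_from_ratio(r: float | np.ndarray, rho: float, psi: float):
    """Invert the purity/ploidy mixture: depth ratio r -> allele copy number."""
    if not 0 < rho <= 1:
        raise ValueError(f"purity {rho} outside (0, 1]")
    return (np.asarray(r, dtype=float) * (rho * psi + 2 * (1 - rho)) / 2 - (1 - rho)) / rho


def ratio_from_copy_number(n: float | np.ndarray, rho: float, psi: float):
    """Forward model: allele copy number n -> expected depth ratio r."""
    if not 0 < rho <= 1:
        raise ValueError(f"purity {rho} outside (0, 1]")
    return 2 * (rho * np.asarray(n, dtype=float) + (1 - rho)) / (rho * psi + 2 * (1 - rho))


def _t_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    mean = float(np.mean(values))
    if values.size < 2:
        return (float("nan"), float("nan"))
    sem = stats.sem(values)
    if sem == 0:
        return (mean, mean)
    lo, hi = stats.t.interval(confidence, df=values.size - 1, loc=mean, scale=sem)
    return (float(lo), float(hi))


def allelic_copy_number(
    tumor: SnpDepthTable,
    germline: SnpDepthTable,
    rho: float,
    psi: float,
    allele_names: tuple[str, str] = ("allele1", "allele2"),
) -> tuple[CopyNumberResult, CopyNumberResult]:
    """Per-allele copy number with a 95% t-interval over per-SNP estimates.

    SNPs with zero germline depth for an allele are excluded from that
    allele's ratio.  Negative per-SNP estimates are kept before averaging
    (they carry information about sampling noise); the reported mean is
    floored at zero.
    """
    merged = tumor.df.merge(
        germline.df, on="snp_id", suffixes=("_t", "_n"), validate="one_to_one"
    )
    if len(merged) < 2:
        raise ValueError("need at least two shared SNPs to estimate copy number")
    results = []
    for i, name in enumerate(allele_names, start=1):
        dt = merged[f"depth_allele{i}_t"].to_numpy(dtype=float)
        dn = merged[f"depth_allele{i}_n"].to_numpy(dtype=float)
        usable = dn > 0
        r = (dt[usable] / tumor.library_size) / (dn[usable] / germline.library_size)
        n_i = copy_number_from_ratio(r, rho, psi)
        mean = float(np.mean(n_i))
        lo, hi = _t_ci(n_i)
        results.append(
            CopyNumberResult(
                allele=name,
                n_snps=int(usable.sum()),
                cn=max(0.0, mean),
                cn_raw=mean,
                ci_low=lo,
                ci_high=hi,
                ci_width=hi - lo,
            )
        )
    return results[0], results[1]


def dna_aib_test(tumor: SnpDepthTable, min_snps: int = MIN_SNPS) -> tuple[float, str]:
    """Two-sided paired Wilcoxon signed-rank test of DNA allelic imbalance.

    Returns (p-value, major allele label), the major allele being the one
    with the higher total depth.  All-tied depths give p = 1.
    """
    if tumor.n_snps < min_snps:
        raise ValueError(f"need >= {min_snps} SNPs, got {tumor.n_snps}")
    d1 = tumor.df.depth_allele1.to_numpy(dtype=float)
    d2 = tumor.df.depth_allele2.to_numpy(dtype=float)
    p = wilcoxon_paired(d1, d2, alternative="two-sided")
    major = "allele1" if d1.sum() >= d2.sum() else "allele2"
    return p, major


def call_loh(
    result1: CopyNumberResult,
    result2: CopyNumberResult,
    aib_pvalue: float,
    cn_threshold: float = LOH_CN_THRESHOLD,
    p_threshold: float = LOH_P_THRESHOLD,
) -> tuple[CopyNumberResult, CopyNumberResult]:
    """Flag LOH (one allele lost) and biallelic loss (homozygous deletion).

    An allele is under LOH when its copy number falls below ``cn_threshold``
    with significant allelic imbalance.  When both alleles fall below the
    threshold the event is a biallelic loss, which supersedes LOH.
    """
    both_low = result1.cn < cn_threshold and result2.cn < cn_threshold
    for res in (result1, result2):
        res.aib_pvalue = aib_pvalue
        if both_low:
            res.biallelic_loss = True
            res.loh = False
        else:
            res.biallelic_loss = False
            res.loh = res.cn < cn_threshold and aib_pvalue < p_threshold
    return result1, result2


def expected_depth(tumor: SnpDepthTable, rho: float, cn: float, allele: int) -> float:
    """Mean depth attributable to cancer cells for one allele.

    Scales each tumor SNP depth by the fraction of DNA copies contributed by
    cancer cells, rho*n / (rho*n + (1-rho)); with purity 1 this is simply
    the mean tumor depth.
    """
    n = max(0.0, cn)
    d = tumor.df[f"depth_allele{allele}"].to_numpy(dtype=float)
    denom = rho * n + (1 - rho)
    if denom == 0:
        return 0.0
    return float(np.mean(d) * rho * n / denom)


def dna_gene_filters(
    n_snps: int,
    expected_depths: tuple[float, float],
    ci_widths: tuple[float, float],
    min_snps: int = MIN_SNPS,
    min_expected_depth: float = MIN_EXPECTED_DEPTH,
    max_ci_width: float = MAX_CI_WIDTH,
) -> tuple[bool, list[str]]:
    """Gene-level DNA evaluability: enough SNPs, enough cancer-cell depth on
    both alleles, and a narrow copy-number confidence interval."""
    reasons: list[str] = []
    if n_snps < min_snps:
        reasons.append(f"min_snps: {n_snps} < {min_snps}")
    for i, depth in enumerate(expected_depths, start=1):
        if depth < min_expected_depth:
            reasons.append(f"expected_depth allele{i}: {depth:.2f} < {min_expected_depth}")
    for i, width in enumerate(ci_widths, start=1):
        if not width < max_ci_width:
            reasons.append(f"ci_width allele{i}: {width:.3f} >= {max_ci_width}")
    return (not reasons, reasons)


def analyze_gene_dna(
    tumor: SnpDepthTable,
    germline: SnpDepthTable,
    rho: float,
    psi: float,
    allele_names: tuple[str, str] = ("allele1", "allele2"),
    min_snps: int = MIN_SNPS,
) -> tuple[CopyNumberResult, CopyNumberResult]:
    """Full DNA pipeline for one gene: copy number, AIB, LOH, expected depth
    and evaluability flags."""
    res1, res2 = allelic_copy_number(tumor, germline, rho, psi, allele_names)
    aib_p, _ = dna_aib_test(tumor, min_snps=2)
    call_loh(res1, res2, aib_p)
    res1.expected_depth = expected_depth(tumor, rho, res1.cn, allele=1)
    res2.expected_depth = expected_depth(tumor, rho, res2.cn, allele=2)
    evaluable, reasons = dna_gene_filters(
        n_snps=tumor.n_snps,
        expected_depths=(res1.expected_depth, res2.expected_depth),
        ci_widths=(res1.ci_width, res2.ci_width),
        min_snps=min_snps,
    )
    for res in (res1, res2):
        res.evaluable = evaluable
        res.filter_reasons = list(reasons)
    return res1, res2


# ---------------------------------------------------------------------------
# Somatic mutations


def classify_mutation(
    allele: str,
    position: int,
    consequences: Sequence[str],
    filter_status: str,
    alt_depth: int,
    gene_evaluable: bool = True,
) -> MutationCall:
    """Classify a VEP-annotated somatic call as damaging or not.

    Damaging requires a PASS filter, at least ten alternate-allele reads, a
    high-impact consequence (stop gained/lost, start lost or frameshift) and
    a gene that passes the DNA filters.
    """
    terms = tuple(consequences)
    damaging = (
        filter_status == "PASS"
        and alt_depth >= MIN_ALT_DEPTH
        and bool(set(terms) & DAMAGING_CONSEQUENCES)
        and gene_evaluable
    )
    return MutationCall(
        allele=allele,
        position=position,
        consequences=terms,
        filter_status=filter_status,
        alt_depth=alt_depth,
        damaging=damaging,
    )


def _csq_consequence_index(header: pysam.VariantHeader) -> int:
    """Locate the Consequence slot in the VEP CSQ Format string."""
    rec = header.info.get("CSQ")
    if rec is None or not rec.description:
        raise ValueError("VCF lacks a VEP CSQ INFO definition")
    fmt = rec.description.split("Format:")[-1].strip().strip('"')
    fields = [f.strip() for f in fmt.split("|")]
    try:
        return fields.index("Consequence")
    except ValueError as exc:
        raise ValueError("CSQ Format has no Consequence field") from exc


def classify_mutations_from_vcf(
    vcf_path: str | Path,
    gene_evaluable: dict[str, bool] | None = None,
    sample: str | None = None,
) -> list[MutationCall]:
    """Read a VEP-annotated VCF on HLA-allele coordinates into MutationCalls.

    VCF positions are 1-based; internal positions are 0-based.  The
    alternate-read depth comes from the AD field of the (tumor) sample.
    Records with a malformed CSQ entry are skipped.
    """
    calls: list[MutationCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        csq_idx = _csq_consequence_index(vcf.header)
        sample_name = sample or (list(vcf.header.samples)[0] if vcf.header.samples else None)
        for rec in vcf:
            csq_entries = rec.info.get("CSQ")
            if csq_entries is None:
                continue
            if isinstance(csq_entries, str):
                csq_entries = (csq_entries,)
            terms: set[str] = set()
            malformed = False
            for entry in csq_entries:
                parts = entry.split("|")
                if len(parts) <= csq_idx:
                    malformed = True
                    break
                terms.update(t for t in parts[csq_idx].split("&") if t)
            if malformed or not terms:
                continue
            if sample_name is not None:
                ad = rec.samples[sample_name].get("AD")
                alt_depth = int(ad[1]) if ad is not None and len(ad) > 1 else 0
            else:
                alt_depth = 0
            filter_status = "PASS" if (not list(rec.filter) or "PASS" in rec.filter) else ";".join(rec.filter)
            evaluable = True
            if gene_evaluable is not None:
                evaluable = gene_evaluable.get(rec.chrom, True)
            calls.append(
                classify_mutation(
                    allele=rec.chrom,
                    position=rec.pos - 1,
                    consequences=sorted(terms),
                    filter_status=filter_status,
                    alt_depth=alt_depth,
                    gene_evaluable=evaluable,
                )
            )
    return calls
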