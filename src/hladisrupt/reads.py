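"""Read-level plumbing: library size, HLA read fishing, mismatch filtering,
multimapping diagnostics and sample QC.

HLA reads are recovered from the input alignment ("fishing") rather than
trusted in place, because reads from a polymorphic allele frequently end up
unmapped, soft-clipped, or on an alternate contig.  After re-alignment to the
patient-specific reference (by an external aligner) the allele-level BAMs are
filtered so that only reads compatible with one allele remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .reference import KmerIndex

WES_MIN_PAIRED_READS = 5_000_000
WES_MIN_ALIGNMENT_RATE = 0.8
RNA_MIN_ALIGNMENT_RATE = 0.6

# contig names counted as "primary, non-HLA" for the fishing criteria
_PRIMARY_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT", "M"}


@dataclass
class LibrarySize:
    sample_id: str
    paired_aligned_reads: int
    include_unmapped: bool = False


@dataclass
class AlleleAlignmentStats:
    """Per-gene multimapping diagnostics over allele-assigned RNA reads."""

    gene: str
    total_reads: int
    fraction_both_alleles: float
    fraction_multi_gene: float


@dataclass
class QcResult:
    sample_id: str
    modality: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    p = str(path)
    mode = "r" if p.endswith(".sam") else "rb"
    return pysam.AlignmentFile(p, mode, check_sq=False)


def compute_library_size(
    alignment_path: str | Path,
    include_unmapped: bool = False,
    sample_id: str | None = None,
) -> LibrarySize:
    """Number of paired, aligned reads in an alignment file.

    Counts primary records that are paired with both mates mapped; with
    ``include_unmapped`` every paired primary record counts.  Used as the
    normalising constant L for depth and RPKM computations.
    """
    n = 0
    with _open_alignment(alignment_path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                continue
            if include_unmapped:
                n += 1
            elif not read.is_unmapped and not read.mate_is_unmapped:
                n += 1
    sid = sample_id or Path(alignment_path).stem
    return LibrarySize(sample_id=sid, paired_aligned_reads=n, include_unmapped=include_unmapped)


def is_candidate_hla_contig(contig: str | None) -> bool:
    """True for chromosome 6 and for any alternate/unplaced contig."""
    if contig is None:
        return False
    name = contig[3:] if contig.lower().startswith("chr") else contig
    if name == "6":
        return True
    return name not in _PRIMARY_CHROMS


def fish_reads(
    alignment_path: str | Path,
    kmer_index: KmerIndex | None,
    unmapped: bool = True,
    contig: bool = True,
    fish: bool = True,
) -> set[str]:
    """Select candidate HLA read pairs from an arbitrary alignment.

    A read pair is kept when either mate is unmapped, maps to chromosome 6
    or an alternate contig, or contains an exact k-mer from the reference
    index.  Returns the set of kept read names (pair granularity).
    """
    if fish and kmer_index is None:
        raise ValueError("fish criterion enabled but no k-mer index supplied")
    kept: set[str] = set()
    with _open_alignment(alignment_path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.query_name in kept:
                continue
            if unmapped and read.is_unmapped:
                kept.add(read.query_name)
                continue
            if contig and not read.is_unmapped and is_candidate_hla_contig(read.reference_name):
                kept.add(read.query_name)
                continue
            if fish and read.query_sequence and kmer_index.read_matches(read.query_sequence):
                kept.add(read.query_name)
    return kept


def write_fished_fastq(
    alignment_path: str | Path,
    read_names: set[str],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Emit both mates of every kept pair as a deterministic FASTQ pair."""
    mates: dict[str, dict[int, tuple[str, str]]] = {}
    with _open_alignment(alignment_path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.query_name not in read_names:
                continue
            seq = read.get_forward_sequence() or read.query_sequence or ""
            quals = read.get_forward_qualities() or read.query_qualities
            qual = "".join(chr(q + 33) for q in quals) if quals is not None else "I" * len(seq)
            mate = 2 if read.is_paired and read.is_read2 else 1
            mates.setdefault(read.query_name, {})[mate] = (seq, qual)
    out1 = Path(f"{out_prefix}_1.fastq")
    out2 = Path(f"{out_prefix}_2.fastq")
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for name in sorted(mates):
            pair = mates[name]
            if 1 in pair:
                f1.write(f"@{name}/1\n{pair[1][0]}\n+\n{pair[1][1]}\n")
            if 2 in pair:
                f2.write(f"@{name}/2\n{pair[2][0]}\n+\n{pair[2][1]}\n")
    return out1, out2


def mismatch_count(read: pysam.AlignedSegment) -> int:
    """Substitution count: edit distance (NM) minus inserted/deleted bases."""
    if not read.has_tag("NM"):
        raise ValueError(f"read {read.query_name!r} lacks an NM (edit distance) tag")
    nm = read.get_tag("NM")
    indel_bases = sum(
        length for op, length in (read.cigartuples or []) if op in (1, 2)  # I, D
    )
    return int(nm) - indel_bases


def has_indel(read: pysam.AlignedSegment) -> bool:
    return any(op in (1, 2) for op, _ in (read.cigartuples or []))


def filter_allele_alignment(
    records: Iterable[pysam.AlignedSegment], max_mismatch: int = 1
) -> Iterator[pysam.AlignedSegment]:
    """Drop reads with more than ``max_mismatch`` substitutions against the
    allele reference, and any read containing an indel.

    An indel against the patient's own allele sequence indicates the read
    belongs to the other allele (or is erroneous), so such reads are removed
    outright rather than counted as mismatches.
    """
    for read in records:
        if read.is_unmapped:
            continue
        if has_indel(read):
            continue
        if mismatch_count(read) > max_mismatch:
            continue
        yield read


def filter_alignment_file(
    in_path: str | Path, out_path: str | Path, max_mismatch: int = 1
) -> int:
    """File-level wrapper around :func:`filter_allele_alignment`; returns the
    number of retained records."""
    kept = 0
    with _open_alignment(in_path) as af:
        out_mode = "w" if str(out_path).endswith(".sam") else "wb"
        with pysam.AlignmentFile(str(out_path), out_mode, template=af) as out:
            for read in filter_allele_alignment(af.fetch(until_eof=True), max_mismatch):
                out.write(read)
                kept += 1
    return kept


def multimapping_fractions(
    best_alignments: dict[str, set[str]],
    allele_to_gene: dict[str, str],
) -> dict[str, AlleleAlignmentStats]:
    """Multimapping diagnostics from a per-read best-alignment table.

    ``best_alignments`` maps read name -> set of allele references sharing
    the best alignment score.  A read is assigned to a gene when any best
    alignment hits an allele of that gene; it counts toward
    ``fraction_both_alleles`` when its best set contains both alleles of the
    gene, and toward ``fraction_multi_gene`` when it spans more than one
    HLA gene.
    """
    genes = sorted(set(allele_to_gene.values()))
    alleles_by_gene: dict[str, set[str]] = {g: set() for g in genes}
    for allele, gene in allele_to_gene.items():
        alleles_by_gene[gene].add(allele)

    stats: dict[str, AlleleAlignmentStats] = {}
    for gene in genes:
        total = 0
        both = 0
        multi = 0
        for best in best_alignments.values():
            hit_genes = {allele_to_gene[a] for a in best if a in allele_to_gene}
            if gene not in hit_genes:
                continue
            total += 1
            if len(alleles_by_gene[gene] & best) >= 2:
                both += 1
            if len(hit_genes) > 1:
                multi += 1
        stats[gene] = AlleleAlignmentStats(
            gene=gene,
            total_reads=total,
            fraction_both_alleles=both / total if total else 0.0,
            fraction_multi_gene=multi / total if total else 0.0,
        )
    return stats


def sample_qc(
    library_size: LibrarySize | int, alignment_rate: float, modality: str
) -> QcResult:
    """Sample-level inclusion thresholds.

    WES samples need at least 5,000,000 paired aligned reads and an
    alignment rate of at least 0.8; RNA-seq samples need an alignment rate
    of at least 0.6.  Thresholds are strict "less than" exclusions, so a
    sample exactly at a threshold passes.
    """
    if not 0.0 <= alignment_rate <= 1.0:
        raise ValueError(f"alignment rate {alignment_rate} outside [0, 1]")
    n_reads = (
        library_size.paired_aligned_reads
        if isinstance(library_size, LibrarySize)
        else int(library_size)
    )
    sid = library_size.sample_id if isinstance(library_size, LibrarySize) else "sample"
    reasons: list[str] = []
    if modality == "wes":
        if n_reads < WES_MIN_PAIRED_READS:
            reasons.append(
                f"paired aligned reads {n_reads} < {WES_MIN_PAIRED_READS}"
            )
        if alignment_rate < WES_MIN_ALIGNMENT_RATE:
            reasons.append(f"alignment rate {alignment_rate} < {WES_MIN_ALIGNMENT_RATE}")
    elif modality == "rna":
        if alignment_rate < RNA_MIN_ALIGNMENT_RATE:
            reasons.append(f"alignment rate {alignment_rate} < {RNA_MIN_ALIGNMENT_RATE}")
    else:
        raise ValueError(f"unknown modality {modality!r} (expected 'wes' or 'rna')")
    return QcResult(sample_id=sid, modality=modality, passed=not reasons, reasons=reasons)
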