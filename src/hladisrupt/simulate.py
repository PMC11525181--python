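"""Synthetic-data generation with known ground truth.

Every stage of the toolkit is testable without external downloads: a toy
allele database stands in for the IMGT/HLA allele catalogue, count-level
simulators exercise the copy-number and expression machinery under the
Poisson depth model, and a read-level simulator produces spliced alignments
with a known alternative-splicing proportion.

All generators are deterministic under their seed and serialise their
ground truth alongside the generated data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .dna import SnpDepthTable, ratio_from_copy_number
from .reference import AlleleModel, Feature, SpliceModification

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
DEFAULT_LIBRARY_SIZE = 1_000_000


@dataclass
class SimulationTruth:
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Toy allele database


def _random_cds_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return codons


def _mutate_allele(
    rng: np.random.Generator,
    base_seq: str,
    features: list[Feature],
    snp_rate: float,
) -> str:
    """Substitute bases at ``snp_rate`` without breaking the reading frame.

    Intronic positions mutate freely.  Exonic positions mutate only when the
    new codon is neither a stop nor disturbs the start/stop codons, keeping
    every allele's CDS translatable.
    """
    seq = list(base_seq)
    exon_positions: list[int] = []
    for f in features:
        if f.kind == "exon":
            exon_positions.extend(range(f.start, f.end))
    cds_index = {pos: i for i, pos in enumerate(exon_positions)}
    n_codons = len(exon_positions) // 3

    n_subs = rng.binomial(len(seq), snp_rate)
    candidates = rng.permutation(len(seq))
    placed = 0
    for pos in candidates:
        if placed >= n_subs:
            break
        pos = int(pos)
        alternatives = [b for b in BASES if b != seq[pos]]
        rng.shuffle(alternatives)
        if pos not in cds_index:
            seq[pos] = alternatives[0]
            placed += 1
            continue
        ci = cds_index[pos] // 3
        if ci == 0 or ci == n_codons - 1:  # preserve start and stop codons
            continue
        offset = cds_index[pos] % 3
        codon_positions = exon_positions[3 * ci : 3 * ci + 3]
        codon = [seq[p] for p in codon_positions]
        for alt in alternatives:
            trial = codon.copy()
            trial[offset] = alt
            if "".join(trial) not in STOP_CODONS:
                seq[pos] = alt
                placed += 1
                break
    return "".join(seq)


def make_toy_allele_db(
    seed: int,
    n_genes: int = 3,
    alleles_per_gene: int = 4,
    exons: int = 4,
    exon_len: int = 99,
    intron_len: int = 100,
    snp_rate: float = 0.02,
) -> tuple[dict[str, AlleleModel], SimulationTruth]:
    """Generate a toy allele database emulating the IMGT catalogue.

    Each gene gets a random base sequence of alternating exons and introns;
    alleles of a gene differ from the base only by substitutions drawn at
    ``snp_rate`` per base, so allele pairs differ at roughly
    ``2 * snp_rate * length`` positions.  Every allele's CDS begins with ATG
    and ends with a stop codon.  Exon length defaults to 99 so the coding
    frame closes without UTRs.
    """
    rng = np.random.default_rng(seed)
    gene_letters = ["A", "B", "C"][:n_genes]
    db: dict[str, AlleleModel] = {}
    truth_alleles: dict[str, list[str]] = {}

    for letter in gene_letters:
        total_exonic = exons * exon_len
        if total_exonic % 3:
            raise ValueError("total exonic length must be a codon multiple")
        codons = _random_cds_codons(rng, total_exonic // 3)
        cds = "".join(codons)
        features: list[Feature] = []
        seq_parts: list[str] = []
        pos = 0
        cds_cursor = 0
        for i in range(exons):
            features.append(Feature("exon", i + 1, pos, pos + exon_len))
            seq_parts.append(cds[cds_cursor : cds_cursor + exon_len])
            cds_cursor += exon_len
            pos += exon_len
            if i < exons - 1:
                inner = "".join(rng.choice(list(BASES), intron_len - 4))
                seq_parts.append("GT" + inner + "AG")
                features.append(Feature("intron", i + 1, pos, pos + intron_len))
                pos += intron_len
        base_seq = "".join(seq_parts)

        names = [f"{letter}*{i + 1:02d}:01" for i in range(alleles_per_gene)]
        truth_alleles[f"HLA-{letter}"] = names
        for name in names:
            allele_seq = (
                base_seq if snp_rate == 0 else _mutate_allele(rng, base_seq, features, snp_rate)
            )
            db[name] = AlleleModel(
                allele_name=name,
                gene=f"HLA-{letter}",
                sequence=allele_seq,
                features=[Feature(f.kind, f.index, f.start, f.end) for f in features],
                cds_start=0,
            )

    truth = SimulationTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "alleles_per_gene": alleles_per_gene,
            "exons": exons,
            "exon_len": exon_len,
            "intron_len": intron_len,
            "snp_rate": snp_rate,
            "alleles": truth_alleles,
        },
    )
    return db, truth


def write_allele_db(db: dict[str, AlleleModel], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the database in the FASTA + feature-TSV interchange format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "allele_db.fasta"
    tsv = out / "allele_db_features.tsv"
    with open(fasta, "w") as fh:
        for name in sorted(db):
            fh.write(f">{name}\n")
            seq = db[name].sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(tsv, "w") as fh:
        fh.write("allele_name\tkind\tindex\tstart\tend\tcds_start\n")
        for name in sorted(db):
            a = db[name]
            for f in a.features:
                fh.write(f"{name}\t{f.kind}\t{f.index}\t{f.start}\t{f.end}\t{a.cds_start}\n")
    return fasta, tsv


# ---------------------------------------------------------------------------
# Count-level simulators


def simulate_dna_depths(
    copy_numbers: tuple[float, float],
    rho: float,
    psi: float,
    n_snps: int = 20,
    mean_depth: float = 60.0,
    seed: int = 0,
    library_size: int = DEFAULT_LIBRARY_SIZE,
) -> tuple[SnpDepthTable, SnpDepthTable]:
    """Poisson germline and tumor SNP depth tables under the mixture model.

    Germline allele depths are Poisson(mean_depth / 2); tumor allele depths
    are Poisson(mean_depth * (rho * n_a + (1 - rho)) / (rho * psi + 2 (1 - rho))),
    i.e. the forward model whose ratio the copy-number estimator inverts.
    Returns (germline, tumor); both carry the same library size so the
    depth ratio is the copy-number signal.
    """
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "snp_id": range(n_snps),
            "pos_allele1": range(0, 10 * n_snps, 10),
            "pos_allele2": range(0, 10 * n_snps, 10),
            "region": "exon",
        }
    )
    germ = frame.copy()
    tum = frame.copy()
    for i, n_a in enumerate(copy_numbers, start=1):
        germ[f"depth_allele{i}"] = rng.poisson(mean_depth / 2, n_snps)
        tumor_mean = mean_depth / 2 * ratio_from_copy_number(n_a, rho, psi)
        tum[f"depth_allele{i}"] = rng.poisson(tumor_mean, n_snps)
    return (
        SnpDepthTable("germline", library_size, germ),
        SnpDepthTable("tumor", library_size, tum),
    )


def simulate_expression_depths(
    knockdown: tuple[float, float] = (1.0, 1.0),
    n_snps: int = 10,
    mean_depth: float = 50.0,
    seed: int = 0,
    library_size: int = DEFAULT_LIBRARY_SIZE,
) -> tuple[SnpDepthTable, SnpDepthTable]:
    """Matched normal and tumor exonic RNA depth tables.

    ``knockdown`` scales each allele's tumor expression relative to normal
    (1.0 = unchanged, 0.2 = 80% knockdown).  Returns (normal, tumor).
    """
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "snp_id": range(n_snps),
            "pos_allele1": range(0, 10 * n_snps, 10),
            "pos_allele2": range(0, 10 * n_snps, 10),
            "region": "exon",
        }
    )
    normal = frame.copy()
    tumor = frame.copy()
    for i, factor in enumerate(knockdown, start=1):
        normal[f"depth_allele{i}"] = rng.poisson(mean_depth, n_snps)
        tumor[f"depth_allele{i}"] = rng.poisson(mean_depth * factor, n_snps)
    return (
        SnpDepthTable("normal", library_size, normal),
        SnpDepthTable("tumor", library_size, tumor),
    )


# ---------------------------------------------------------------------------
# Read-level RNA simulator


def _transcript_positions(
    model: AlleleModel, modification: SpliceModification | None
) -> list[int]:
    kept = set(model.mature_transcript_positions())
    if modification is not None:
        rng_ = set(range(modification.start, modification.end))
        kept = kept - rng_ if modification.kind == "skip" else kept | rng_
    return sorted(kept)


def _positions_to_cigar(positions: Sequence[int]) -> tuple[int, list[tuple[int, int]]]:
    """Reference start and CIGAR (M/N runs) for a read covering the given
    consecutive transcript positions."""
    start = positions[0]
    cigar: list[tuple[int, int]] = []
    run_start = positions[0]
    prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        cigar.append((0, prev - run_start + 1))  # M
        cigar.append((3, p - prev - 1))  # N
        run_start = p
        prev = p
    cigar.append((0, prev - run_start + 1))
    return start, cigar


def simulate_rna_reads(
    model: AlleleModel,
    out_sam: str | Path,
    splice_modification: SpliceModification | None = None,
    splice_proportion: float = 0.0,
    depth: float = 200.0,
    read_length: int = 100,
    seed: int = 0,
    substitution_rate: float = 0.0,
    out_fastq_prefix: str | Path | None = None,
) -> SimulationTruth:
    """Simulate spliced single-end alignments (and optionally FASTQ pairs).

    Each fragment is drawn from the modified transcript with probability
    ``splice_proportion``, otherwise from the canonical transcript, with a
    uniform start.  Reads are error-free by default; a substitution rate is
    available for mismatch-filter exercises.  Alignment records carry the
    exact CIGAR (M/N) implied by the transcript-to-genome map, emulating
    the output of a spliced aligner on error-free reads.
    """
    rng = np.random.default_rng(seed)
    canonical = _transcript_positions(model, None)
    modified = (
        _transcript_positions(model, splice_modification)
        if splice_modification is not None
        else canonical
    )
    n_reads = int(depth * len(canonical) / read_length)
    # Uniform fragmentation yields reads in proportion to transcript
    # abundance times the number of fragment start positions, so a read
    # comes from the novel transcript with the length-weighted probability
    # (this is what makes junction-count ratios estimate the transcript
    # proportion without length bias).
    w_novel = splice_proportion * max(0, len(modified) - read_length + 1)
    w_canon = (1 - splice_proportion) * max(0, len(canonical) - read_length + 1)
    p_read_novel = w_novel / (w_novel + w_canon) if w_novel + w_canon > 0 else 0.0

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": model.allele_name, "LN": len(model.sequence)}],
        }
    )
    fq1 = open(f"{out_fastq_prefix}_1.fastq", "w") if out_fastq_prefix else None
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        for i in range(n_reads):
            use_novel = (
                splice_modification is not None and rng.random() < p_read_novel
            )
            positions = modified if use_novel else canonical
            if len(positions) < read_length:
                continue
            start = int(rng.integers(0, len(positions) - read_length + 1))
            window = positions[start : start + read_length]
            seq = list(model.sequence[p] for p in window)
            if substitution_rate > 0:
                for j in range(read_length):
                    if rng.random() < substitution_rate:
                        seq[j] = rng.choice([b for b in BASES if b != seq[j]])
            ref_start, cigar = _positions_to_cigar(window)
            read = pysam.AlignedSegment(header)
            read.query_name = f"sim_{model.allele_name}_{i}"
            read.query_sequence = "".join(seq)
            read.flag = 0
            read.reference_id = 0
            read.reference_start = ref_start
            read.mapping_quality = 60
            read.cigartuples = cigar
            read.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            read.set_tag("NM", sum(1 for a, b in zip(seq, (model.sequence[p] for p in window)) if a != b))
            read.set_tag("NH", 1)
            out.write(read)
            if fq1 is not None:
                fq1.write(
                    f"@sim_{model.allele_name}_{i}\n{''.join(seq)}\n+\n{'I' * read_length}\n"
                )
    if fq1 is not None:
        fq1.close()
    return SimulationTruth(
        seed=seed,
        params={
            "allele": model.allele_name,
            "splice_proportion": splice_proportion,
            "modification": None
            if splice_modification is None
            else asdict(splice_modification),
            "depth": depth,
            "read_length": read_length,
            "n_reads": n_reads,
        },
    )


# ---------------------------------------------------------------------------
# Neoantigen table


def simulate_neoantigen_table(
    allele_names: Sequence[str],
    n_mutations: int,
    binder_fraction: float,
    seed: int = 0,
    peptides_per_mutation: int = 3,
) -> pd.DataFrame:
    """Neoantigen-allele binding table with a known binder fraction.

    Each (mutation, allele) pair binds (best peptide rank drawn in
    [0, 0.5]) with probability ``binder_fraction``; otherwise all its
    peptide ranks fall above the cutoff.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mutations):
        for allele in allele_names:
            binds = rng.random() < binder_fraction
            for pidx in range(peptides_per_mutation):
                if binds and pidx == 0:
                    rank = float(rng.uniform(0.0, 0.5))
                else:
                    rank = float(rng.uniform(0.6, 50.0))
                rows.append(
                    {
                        "mutation_id": f"mut{m}",
                        "peptide": f"PEP{m}_{pidx}",
                        "allele": allele,
                        "rank": round(rank, 4),
                    }
                )
    return pd.DataFrame(rows)
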