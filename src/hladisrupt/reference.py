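"""Patient-specific HLA reference construction.

The class I HLA genes (HLA-A, HLA-B, HLA-C) are the most polymorphic loci in
the human genome, so reads from these genes align poorly to a generic genome
reference.  All allele-specific analyses therefore run against a
patient-specific reference built from the genomic sequences of the patient's
six typed alleles.  This module parses an allele database (FASTA of genomic
allele sequences plus a TSV of exon/intron features), assembles patient
references, derives canonical splice junctions, and builds the k-mer index
used to "fish" candidate HLA reads out of an arbitrary alignment.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

CLASS_I_GENES = ("HLA-A", "HLA-B", "HLA-C")

DEFAULT_KMER_LENGTH = 30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Raised when the allele database violates its structural contract."""


@dataclass(frozen=True)
class Feature:
    """One exon, intron or UTR of an allele, in allele coordinates."""

    kind: str  # 'exon' | 'intron' | 'utr'
    index: int  # 1-based ordinal within its kind
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron", "utr"):
            raise ReferenceError(f"unknown feature kind {self.kind!r}")
        if self.end <= self.start:
            raise ReferenceError(
                f"empty/inverted feature interval [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlleleModel:
    """One HLA allele: genomic sequence plus its exon/intron structure.

    ``sequence`` is the genomic (unspliced) allele sequence on the coding
    strand, 5'->3'.  ``features`` tile the sequence without gaps or overlap;
    exons and introns alternate.  ``cds_start`` is the allele coordinate of
    the A of the start codon.
    """

    allele_name: str
    gene: str
    sequence: str
    features: list[Feature]
    cds_start: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.gene not in CLASS_I_GENES:
            raise ReferenceError(
                f"{self.allele_name}: gene {self.gene!r} is not a class I HLA gene"
            )
        feats = sorted(self.features, key=lambda f: f.start)
        pos = 0
        for f in feats:
            if f.start > pos:
                raise ReferenceError(
                    f"{self.allele_name}: gap [{pos}, {f.start}) between features"
                )
            if f.start < pos:
                raise ReferenceError(
                    f"{self.allele_name}: overlapping feature at [{f.start}, {f.end})"
                )
            pos = f.end
        if pos != len(self.sequence):
            raise ReferenceError(
                f"{self.allele_name}: features end at {pos}, "
                f"sequence length is {len(self.sequence)}"
            )
        exints = [f for f in feats if f.kind in ("exon", "intron")]
        for a, b in zip(exints, exints[1:]):
            if a.kind == b.kind:
                raise ReferenceError(
                    f"{self.allele_name}: adjacent {a.kind}s at {a.interval} / {b.interval}"
                )
        exon_idx = [f.index for f in feats if f.kind == "exon"]
        if exon_idx != sorted(exon_idx) or len(set(exon_idx)) != len(exon_idx):
            raise ReferenceError(f"{self.allele_name}: exon indices not strictly increasing")
        self.features = feats

    @property
    def exons(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "exon"]

    @property
    def introns(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "intron"]

    def feature_at(self, pos: int) -> Feature:
        for f in self.features:
            if f.start <= pos < f.end:
                return f
        raise ReferenceError(f"{self.allele_name}: position {pos} outside gene body")

    @property
    def exonic_length(self) -> int:
        return sum(len(f) for f in self.exons)

    def mature_transcript_positions(self) -> list[int]:
        """Allele coordinates retained in the canonically spliced transcript."""
        out: list[int] = []
        for f in self.exons:
            out.extend(range(f.start, f.end))
        return out


@dataclass
class PatientReference:
    """The up-to-six allele reference for one patient.

    A gene whose two typed allele names are identical is homozygous; such
    genes are excluded from allele-specific analyses (there are no
    allele-distinguishing SNPs) but kept for gene-level outputs.
    """

    patient_id: str
    alleles: list[AlleleModel]
    homozygous_genes: set[str] = field(default_factory=set)
    kmer_length: int = DEFAULT_KMER_LENGTH

    def allele(self, name: str) -> AlleleModel:
        for a in self.alleles:
            if a.allele_name == name:
                return a
        raise KeyError(name)

    def alleles_of(self, gene: str) -> list[AlleleModel]:
        return [a for a in self.alleles if a.gene == gene]


@dataclass(frozen=True)
class SpliceModification:
    """A deviation from canonical splicing, in allele coordinates.

    ``skip``   — the interval is spliced out in addition to the introns
                 (exonic bases inside it are lost from the transcript).
    ``retain`` — intronic bases inside the interval stay in the transcript.
    """

    kind: str  # 'skip' | 'retain'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("skip", "retain"):
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("empty modification interval")


# ---------------------------------------------------------------------------
# Allele database parsing


def _infer_gene(allele_name: str) -> str:
    locus = allele_name.split("*")[0]
    gene = locus if locus.startswith("HLA-") else f"HLA-{locus}"
    if gene not in CLASS_I_GENES:
        raise ReferenceError(f"cannot map allele {allele_name!r} to a class I gene")
    return gene


def parse_allele_db(
    fasta_path: str | Path, features_path: str | Path
) -> dict[str, AlleleModel]:
    """Parse an allele database into :class:`AlleleModel` objects.

    The feature table is tab-separated with a header row and columns
    ``allele_name, kind, index, start, end`` (0-based half-open) and an
    optional ``cds_start`` column.  Every FASTA record must have a feature
    block; every model is validated on construction.  Alleles are returned
    in deterministic (sorted-name) order.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    feats: dict[str, list[Feature]] = {}
    cds_starts: dict[str, int] = {}
    with open(features_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = row["allele_name"]
            feats.setdefault(name, []).append(
                Feature(
                    kind=row["kind"],
                    index=int(row["index"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
            if "cds_start" in row and row["cds_start"] not in (None, ""):
                cds_starts[name] = int(row["cds_start"])

    db: dict[str, AlleleModel] = {}
    for name in sorted(records):
        if name not in feats:
            raise ReferenceError(f"allele {name!r} has no entries in the feature table")
        db[name] = AlleleModel(
            allele_name=name,
            gene=_infer_gene(name),
            sequence=records[name],
            features=feats[name],
            cds_start=cds_starts.get(name, 0),
        )
    extra = set(feats) - set(records)
    if extra:
        raise ReferenceError(
            f"feature table references alleles missing from FASTA: {sorted(extra)}"
        )
    return db


def build_patient_reference(
    db: dict[str, AlleleModel],
    six_allele_names: Sequence[str],
    patient_id: str = "patient",
    kmer_length: int = DEFAULT_KMER_LENGTH,
) -> PatientReference:
    """Assemble the patient reference from six typed allele names.

    Names come in gene pairs (A, A, B, B, C, C order is conventional but not
    required).  A gene typed with two identical names is flagged homozygous
    and contributes a single record.
    """
    for name in six_allele_names:
        if name not in db:
            raise ReferenceError(f"unknown allele name {name!r}")
    by_gene: dict[str, list[str]] = {}
    for name in six_allele_names:
        by_gene.setdefault(db[name].gene, []).append(name)
    homozygous = {
        gene for gene, names in by_gene.items() if len(names) == 2 and names[0] == names[1]
    }
    seen: set[str] = set()
    alleles: list[AlleleModel] = []
    for name in six_allele_names:
        if name not in seen:
            alleles.append(db[name])
            seen.add(name)
    return PatientReference(
        patient_id=patient_id,
        alleles=alleles,
        homozygous_genes=homozygous,
        kmer_length=kmer_length,
    )


def write_patient_reference(ref: PatientReference, out_dir: str | Path) -> None:
    """Write ``patient_reference.fasta``, ``patient_features.tsv`` and
    ``canonical_junctions.tsv`` for downstream aligners and modules."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "patient_reference.fasta", "w") as fh:
        for a in ref.alleles:
            fh.write(f">{a.allele_name}\n")
            for i in range(0, len(a.sequence), 60):
                fh.write(a.sequence[i : i + 60] + "\n")
    with open(out / "patient_features.tsv", "w") as fh:
        fh.write("allele_name\tkind\tindex\tstart\tend\tcds_start\n")
        for a in ref.alleles:
            for f in a.features:
                fh.write(
                    f"{a.allele_name}\t{f.kind}\t{f.index}\t{f.start}\t{f.end}\t{a.cds_start}\n"
                )
    with open(out / "canonical_junctions.tsv", "w") as fh:
        fh.write("allele_name\tstart\tend\n")
        for a in ref.alleles:
            for start, end in sorted(canonical_junctions(a)):
                fh.write(f"{a.allele_name}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Exact-membership index of all k-mers (both strands) of a reference."""

    def __init__(self, kmers: set[str], k: int):
        self.kmers = kmers
        self.k = k

    def __contains__(self, kmer: str) -> bool:
        return kmer.upper() in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)

    def read_matches(self, read_sequence: str) -> bool:
        """True if any k-mer of the read is present in the index."""
        seq = read_sequence.upper()
        k = self.k
        if len(seq) < k:
            return False
        return any(seq[i : i + k] in self.kmers for i in range(len(seq) - k + 1))


def build_kmer_index(
    ref: PatientReference | Iterable[AlleleModel], k: int = DEFAULT_KMER_LENGTH
) -> KmerIndex:
    """Index every k-mer of every allele sequence and its reverse complement.

    Reads are unstranded, so matching on both strands lets a single forward
    scan of the read decide membership.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    alleles = ref.alleles if isinstance(ref, PatientReference) else list(ref)
    shortest = min(len(a.sequence) for a in alleles)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest allele length {shortest}")
    kmers: set[str] = set()
    for a in alleles:
        seq = a.sequence.upper()
        rc = reverse_complement(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return KmerIndex(kmers, k)


# ---------------------------------------------------------------------------
# Splice geometry


def canonical_junctions(model: AlleleModel) -> set[tuple[int, int]]:
    """The annotated splice junctions of an allele: one interval per intron."""
    return {f.interval for f in model.introns}


def spliced_cds(model: AlleleModel, modification: SpliceModification | None = None) -> str:
    """Mature coding sequence after (optionally) applying a splice change.

    With no modification this is the concatenated exonic sequence from
    ``cds_start`` to the transcript end.  A ``skip`` removes exonic bases in
    the modification interval; a ``retain`` keeps intronic bases in it.
    """
    n = len(model.sequence)
    if modification is not None and not (
        0 <= modification.start < modification.end <= n
    ):
        raise ValueError(
            f"modification [{modification.start}, {modification.end}) outside gene body"
        )
    kept = set(model.mature_transcript_positions())
    if modification is not None:
        mod_range = range(modification.start, modification.end)
        if modification.kind == "skip":
            kept -= set(mod_range)
        else:  # retain
            kept |= set(mod_range)
    positions = [p for p in sorted(kept) if p >= model.cds_start]
    return "".join(model.sequence[p] for p in positions)


def translate_cds(cds: str) -> str:
    """Translate to the first stop codon (stop excluded from the protein)."""
    usable = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(usable).translate(to_stop=True))
    return protein
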