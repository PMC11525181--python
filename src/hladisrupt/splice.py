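"""Allele-specific alternative splicing: junction extraction from spliced
alignments, classification of novel junctions, novel transcript proportion,
protein-level consequences, and tumor enrichment/depletion testing.

A splice junction is the genomic interval removed between two aligned read
blocks (the N operation of a spliced CIGAR), in allele coordinates.  A
junction matching an annotated intron is canonical; anything else is a
candidate novel event, classified by where its two boundaries fall
relative to the allele's exon/intron structure:

* complete exon skipping   — both boundaries are annotated splice sites and
  at least one whole exon lies inside the interval;
* partial exon skipping    — one boundary is an annotated splice site, the
  other lies strictly inside an exon (part of that exon is lost);
* partial intron retention — one boundary is an annotated splice site, the
  other lies strictly inside an intron (the remainder of that intron stays
  in the transcript);
* complete intron retention has no junction at all and is detected from
  contiguous unspliced coverage across both intron boundaries.

Junctions overlapping the first or last exon are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from ._stats import bh_adjust
from .reference import AlleleModel, SpliceModification, spliced_cds

MIN_READS_FOCAL = 2
MIN_READS_OTHER_SAMPLE = 20
ENRICHMENT_ALPHA = 0.05
DEFAULT_MIN_SPAN = 10

CATEGORIES = (
    "canonical",
    "complete_exon_skip",
    "partial_exon_skip",
    "partial_intron_retention",
    "complete_intron_retention",
    "excluded",
    "unclassified",
)


@dataclass(frozen=True)
class JunctionCount:
    allele: str
    start: int
    end: int
    unique_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("junction interval must span at least one base")
        if self.unique_reads < 0:
            raise ValueError("negative read count")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Classification:
    category: str
    affected: tuple[tuple[str, int], ...] = ()  # (kind, index) pairs


@dataclass
class SpliceEvent:
    allele: str
    start: int
    end: int
    category: str
    affected: tuple[tuple[str, int], ...] = ()
    consequence: str | None = None  # 'inframe' | 'frameshift' | 'start_lost'
    ptc: bool = False
    unique_reads: int = 0
    canonical_support: float = 0.0
    novel_transcript_proportion: float = float("nan")
    normal_proportion: float = float("nan")
    enrichment: str = "na"  # 'tumor_enriched' | 'tumor_depleted' | 'neither' | 'na'
    pvalue: float = float("nan")
    adjusted_pvalue: float = float("nan")
    purity_scaled_proportion: float = float("nan")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Junction extraction


def _is_unique(read: pysam.AlignedSegment) -> bool:
    if read.is_secondary or read.is_supplementary:
        return False
    if read.has_tag("NH") and read.get_tag("NH") != 1:
        return False
    return True


def junctions_of_read(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Spliced-out intervals (N operations) of one alignment record."""
    out: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N
            out.append((pos, pos + length))
            pos += length
    return out


def extract_junctions(
    alignment: str | Path | Iterable[pysam.AlignedSegment],
    sample_id: str = "sample",
) -> list[JunctionCount]:
    """Count uniquely mapping junction-spanning reads per (allele, interval).

    A read with several splice gaps contributes to each of its junctions.
    Results are sorted by (allele, start, end) for determinism.
    """
    counts: dict[tuple[str, int, int], int] = {}
    if isinstance(alignment, (str, Path)):
        mode = "r" if str(alignment).endswith(".sam") else "rb"
        af = pysam.AlignmentFile(str(alignment), mode, check_sq=False)
        records: Iterable[pysam.AlignedSegment] = af.fetch(until_eof=True)
    else:
        af = None
        records = alignment
    try:
        for read in records:
            if read.is_unmapped or not _is_unique(read):
                continue
            for start, end in junctions_of_read(read):
                key = (read.reference_name, start, end)
                counts[key] = counts.get(key, 0) + 1
    finally:
        if af is not None:
            af.close()
    return [
        JunctionCount(allele=a, start=s, end=e, unique_reads=n, sample_id=sample_id)
        for (a, s, e), n in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# Classification


def classify_junction(
    interval: tuple[int, int], model: AlleleModel
) -> Classification:
    """Classify a junction against the allele's exon/intron annotation."""
    start, end = interval
    n = len(model.sequence)
    if not (0 <= start < end <= n):
        raise ValueError(f"junction [{start}, {end}) outside gene body [0, {n})")

    introns = model.introns
    exons = model.exons
    intron_intervals = [f.interval for f in introns]

    if (start, end) in intron_intervals:
        intron = introns[intron_intervals.index((start, end))]
        return Classification("canonical", (("intron", intron.index),))

    # terminal-exon exclusion: any overlap with the first or last exon
    if exons:
        for terminal in (exons[0], exons[-1]):
            if start < terminal.end and end > terminal.start:
                return Classification("excluded")

    donor_sites = {f.start for f in introns}
    acceptor_sites = {f.end for f in introns}
    annotated = donor_sites | acceptor_sites

    def inside(kind: str, pos: int):
        for f in model.features:
            if f.kind == kind and f.start < pos < f.end:
                return f
        return None

    start_annot = start in annotated
    end_annot = end in annotated

    if start in donor_sites and end in acceptor_sites:
        # boundaries at intron edges can only contain whole exons
        skipped = [f for f in exons if start <= f.start and f.end <= end]
        if skipped:
            return Classification(
                "complete_exon_skip", tuple(("exon", f.index) for f in skipped)
            )

    if start_annot != end_annot:  # exactly one annotated boundary
        internal = end if start_annot else start
        exon = inside("exon", internal)
        if exon is not None:
            return Classification("partial_exon_skip", (("exon", exon.index),))
        intron = inside("intron", internal)
        if intron is not None:
            return Classification("partial_intron_retention", (("intron", intron.index),))

    return Classification("unclassified")


def retained_interval(
    interval: tuple[int, int], model: AlleleModel
) -> tuple[int, int]:
    """The intronic segment kept in the transcript by a partial intron
    retention junction (the unspliced remainder of the intron)."""
    start, end = interval
    for intron in model.introns:
        if intron.start == start and intron.start < end < intron.end:
            return (end, intron.end)
        if intron.end == end and intron.start < start < intron.end:
            return (intron.start, start)
    raise ValueError(f"junction [{start}, {end}) is not a partial intron retention")


def detect_complete_intron_retention(
    unspliced_read_intervals: Sequence[tuple[int, int]],
    model: AlleleModel,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[tuple[int, int]]:
    """Detect fully retained introns from unspliced (gap-free) coverage.

    An intron is called retained when at least one read crosses each of its
    two exon-intron boundaries by ``min_span`` bases on both sides, and no
    intronic base lacks unspliced coverage.  Returns ``(intron_index,
    support)`` pairs, support being the smaller boundary-spanning count.
    """
    cov = np.zeros(len(model.sequence), dtype=int)
    for s, e in unspliced_read_intervals:
        cov[max(0, s) : min(len(cov), e)] += 1
    events: list[tuple[int, int]] = []
    for intron in model.introns:
        if (cov[intron.start : intron.end] == 0).any():
            continue
        left = sum(
            1
            for s, e in unspliced_read_intervals
            if s <= intron.start - min_span and e >= intron.start + min_span
        )
        right = sum(
            1
            for s, e in unspliced_read_intervals
            if s <= intron.end - min_span and e >= intron.end + min_span
        )
        support = min(left, right)
        if support >= 1:
            events.append((intron.index, support))
    return events


# ---------------------------------------------------------------------------
# Novel transcript proportion


def overlapping_canonical_junctions(
    interval: tuple[int, int], model: AlleleModel
) -> list[tuple[int, int]]:
    """Canonical junctions measuring the same splicing decision: the
    annotated introns whose intervals overlap the novel junction."""
    start, end = interval
    return [
        f.interval for f in model.introns if start < f.end and end > f.start
    ]


def novel_transcript_proportion(
    novel_reads: int, canonical_reads: Sequence[float]
) -> float:
    """Relative abundance of the novel transcript.

    The canonical support is the mean of the overlapping canonical
    junctions' unique read counts (one junction for partial events, two for
    a complete exon skip — averaging avoids double-counting the canonical
    transcript pool).  p = novel / (novel + canonical support).
    """
    if len(canonical_reads) == 0:
        raise ValueError("no overlapping canonical junctions")
    support = float(np.mean(canonical_reads))
    total = novel_reads + support
    if total == 0:
        raise ValueError("zero total junction support")
    return novel_reads / total


# ---------------------------------------------------------------------------
# Consequence


def _canonical_stop_offset(model: AlleleModel) -> int | None:
    """Offset (in bases, from cds_start, in mature-transcript coordinates)
    of the first base of the canonical stop codon; None if no stop."""
    cds = spliced_cds(model)
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in ("TAA", "TAG", "TGA"):
            return i
    return None


def splice_consequence(
    category: str, interval: tuple[int, int], model: AlleleModel
) -> tuple[str, bool]:
    """Protein-level consequence of a classified novel splicing event.

    Returns ``(consequence, ptc)`` where consequence is 'inframe',
    'frameshift' or 'start_lost'.  The net coding-length change decides the
    frame; the PTC flag is true when translation of the modified transcript
    terminates strictly before the position of the canonical stop codon.
    """
    if category in ("partial_intron_retention",):
        mod = SpliceModification("retain", *retained_interval(interval, model))
    elif category == "complete_intron_retention":
        mod = SpliceModification("retain", *interval)
    elif category in ("complete_exon_skip", "partial_exon_skip"):
        mod = SpliceModification("skip", *interval)
    else:
        raise ValueError(f"no consequence defined for category {category!r}")

    if mod.kind == "skip" and mod.start <= model.cds_start < mod.end:
        return ("start_lost", False)

    canonical = spliced_cds(model)
    modified = spliced_cds(model, mod)
    delta = len(modified) - len(canonical)
    consequence = "inframe" if delta % 3 == 0 else "frameshift"

    stop_offset = _canonical_stop_offset(model)
    ptc = False
    if stop_offset is not None:
        # genomic position of the canonical stop codon's first base
        canon_positions = [
            p for p in model.mature_transcript_positions() if p >= model.cds_start
        ]
        stop_genomic = canon_positions[stop_offset]
        # its offset within the modified transcript = kept bases before it
        kept = set(model.mature_transcript_positions())
        mod_range = set(range(mod.start, mod.end))
        kept = kept - mod_range if mod.kind == "skip" else kept | mod_range
        mod_positions = [p for p in sorted(kept) if p >= model.cds_start]
        stop_offset_mod = sum(1 for p in mod_positions if p < stop_genomic)
        for i in range(0, len(modified) - 2, 3):
            if modified[i : i + 3] in ("TAA", "TAG", "TGA"):
                ptc = i < stop_offset_mod
                break
    return (consequence, ptc)


# ---------------------------------------------------------------------------
# Enrichment


def enrichment_test(
    tumor_novel: int,
    tumor_canonical: float,
    normal_novel: int,
    normal_canonical: float,
) -> float:
    """Two-sided Fisher's exact p-value on the (novel, canonical) x
    (tumor, normal) junction-read table."""
    table = np.array(
        [
            [tumor_novel, round(tumor_canonical)],
            [normal_novel, round(normal_canonical)],
        ],
        dtype=int,
    )
    if table.sum() == 0:
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def enrichment_call(
    tumor_proportion: float, normal_proportion: float, adjusted_pvalue: float,
    alpha: float = ENRICHMENT_ALPHA,
) -> str:
    if adjusted_pvalue < alpha:
        if tumor_proportion > normal_proportion:
            return "tumor_enriched"
        if tumor_proportion < normal_proportion:
            return "tumor_depleted"
    return "neither"


def purity_scaled_proportion(p_tumor: float, rho: float) -> float:
    """Novel transcript proportion rescaled to the cancer-cell fraction.

    A tumor sample is an admixture of cancer and normal cells; dividing by
    purity estimates the proportion within cancer cells, capped at 1.
    """
    if rho <= 0 or rho > 1:
        raise ValueError(f"purity {rho} outside (0, 1]")
    return min(1.0, p_tumor / rho)


# ---------------------------------------------------------------------------
# Event assembly


def call_splice_events(
    tumor_junctions: Sequence[JunctionCount],
    model: AlleleModel,
    normal_junctions: Sequence[JunctionCount] | None = None,
    rho: float | None = None,
    alpha: float = ENRICHMENT_ALPHA,
) -> list[SpliceEvent]:
    """Classify, quantify and (with a matched normal) enrichment-test every
    novel junction of one allele in one tumor sample.

    Events are keyed by (allele, interval); only classifiable categories
    (complete/partial exon skip, partial intron retention) are returned.
    """
    tumor_by_iv: Mapping[tuple[int, int], int] = {
        j.interval: j.unique_reads for j in tumor_junctions if j.allele == model.allele_name
    }
    normal_by_iv: Mapping[tuple[int, int], int] = {}
    if normal_junctions is not None:
        normal_by_iv = {
            j.interval: j.unique_reads
            for j in normal_junctions
            if j.allele == model.allele_name
        }

    events: list[SpliceEvent] = []
    for interval, reads in sorted(tumor_by_iv.items()):
        cls = classify_junction(interval, model)
        if cls.category in ("canonical", "excluded", "unclassified"):
            continue
        canon_ivs = overlapping_canonical_junctions(interval, model)
        t_canon = [float(tumor_by_iv.get(iv, 0)) for iv in canon_ivs]
        p_t = novel_transcript_proportion(reads, t_canon)
        consequence, ptc = splice_consequence(cls.category, interval, model)
        event = SpliceEvent(
            allele=model.allele_name,
            start=interval[0],
            end=interval[1],
            category=cls.category,
            affected=cls.affected,
            consequence=consequence,
            ptc=ptc,
            unique_reads=reads,
            canonical_support=float(np.mean(t_canon)),
            novel_transcript_proportion=p_t,
        )
        if normal_junctions is not None:
            n_novel = normal_by_iv.get(interval, 0)
            n_canon = [float(normal_by_iv.get(iv, 0)) for iv in canon_ivs]
            n_support = float(np.mean(n_canon))
            p_n = (
                n_novel / (n_novel + n_support) if n_novel + n_support > 0 else 0.0
            )
            event.normal_proportion = p_n
            event.pvalue = enrichment_test(
                reads, event.canonical_support, n_novel, n_support
            )
        events.append(event)

    with_normal = [e for e in events if not np.isnan(e.pvalue)]
    if with_normal:
        adj = bh_adjust([e.pvalue for e in with_normal])
        for e, a in zip(with_normal, adj):
            e.adjusted_pvalue = float(a)
            e.enrichment = enrichment_call(
                e.novel_transcript_proportion, e.normal_proportion, a, alpha
            )
            if e.enrichment == "tumor_enriched" and rho is not None:
                e.purity_scaled_proportion = purity_scaled_proportion(
                    e.novel_transcript_proportion, rho
                )
    return events


# ---------------------------------------------------------------------------
# Cohort filters


def junction_cohort_filters(events: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Patient-level junction evidence filters.

    ``events`` has one row per (patient_id, sample_id, allele, start, end)
    with ``unique_reads`` and, in tumor mode, ``enrichment``.

    normal_cohort: a junction is kept in a sample when it has at least two
    uniquely mapping reads there and at least 20 in another sample of the
    same patient.

    tumor_cohort: a junction is kept when it is tumor-enriched or
    tumor-depleted and reaches 20 uniquely mapping reads in at least one
    sample (tumor region or matched normal) of the patient.
    """
    if mode not in ("normal_cohort", "tumor_cohort"):
        raise ValueError(f"unknown mode {mode!r}")
    key = ["patient_id", "allele", "start", "end"]
    df = events.copy()
    if mode == "normal_cohort":
        keep_rows = []
        for _, group in df.groupby(key, sort=False):
            for idx, row in group.iterrows():
                if row.unique_reads < MIN_READS_FOCAL:
                    continue
                others = group.drop(index=idx)
                if (others.unique_reads >= MIN_READS_OTHER_SAMPLE).any():
                    keep_rows.append(idx)
        return df.loc[keep_rows]
    # tumor_cohort
    max_reads = df.groupby(key).unique_reads.transform("max")
    mask = df.enrichment.isin(["tumor_enriched", "tumor_depleted"]) & (
        max_reads >= MIN_READS_OTHER_SAMPLE
    )
    return df[mask]
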