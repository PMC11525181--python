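"""Integration of per-allele disruption calls: intact allele counts,
effective neoantigen burden, heterogeneity/convergence across tumor
regions, and the Danaher CD8 T cell infiltration score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

BINDER_RANK_CUTOFF = 0.5
MECHANISMS = ("mutation", "loh", "repression", "splicing")
LOG2_EPSILON = 0.01


@dataclass
class AlleleFlags:
    """Disruption status of one allele in one tumor region."""

    allele: str
    damaging_mutation: bool = False
    loh: bool = False
    biallelic_loss: bool = False
    repressed: bool = False  # genomically unexplained repression
    tumor_enriched_splice: bool = False

    @property
    def genomically_lost(self) -> bool:
        return self.damaging_mutation or self.loh or self.biallelic_loss


@dataclass
class RegionDisruptionSummary:
    patient_id: str
    region: str
    alleles: list[AlleleFlags]
    evaluable: bool = True
    intact_counts: tuple[int, int, int] | None = None  # (none, loh, loh+repression)
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class NeoantigenRecord:
    mutation_id: str
    peptide: str
    allele: str
    eluted_ligand_rank: float

    @property
    def binder(self) -> bool:
        return self.eluted_ligand_rank <= BINDER_RANK_CUTOFF


def intact_allele_count(alleles: Sequence[AlleleFlags], mode: str) -> int:
    """Number of intact alleles (of six) under a disruption-accounting mode.

    'none'           — no mechanism subtracted (always 6);
    'loh'            — subtract alleles lost genomically (LOH, biallelic
                       loss or a damaging mutation);
    'loh+repression' — additionally subtract transcriptionally repressed
                       alleles.  A multiply disrupted allele counts once.
    """
    if mode not in ("none", "loh", "loh+repression"):
        raise ValueError(f"unknown accounting mode {mode!r}")
    total = 6
    if mode == "none":
        return total
    disrupted = 0
    for a in alleles:
        if a.genomically_lost:
            disrupted += 1
        elif mode == "loh+repression" and a.repressed:
            disrupted += 1
    return total - disrupted


def summarize_region(
    patient_id: str,
    region: str,
    alleles: Sequence[AlleleFlags],
    genes_evaluable: Mapping[str, bool] | None = None,
) -> RegionDisruptionSummary:
    """Region-level intact-count triple; NA (None) when any gene is
    unevaluable, with reasons recorded."""
    reasons = []
    if genes_evaluable is not None:
        reasons = [f"{g}: not evaluable" for g, ok in sorted(genes_evaluable.items()) if not ok]
    summary = RegionDisruptionSummary(
        patient_id=patient_id,
        region=region,
        alleles=list(alleles),
        evaluable=not reasons,
        reasons=reasons,
    )
    if summary.evaluable:
        summary.intact_counts = (
            intact_allele_count(alleles, "none"),
            intact_allele_count(alleles, "loh"),
            intact_allele_count(alleles, "loh+repression"),
        )
    return summary


def effective_neoantigen_burden(
    records: Iterable[NeoantigenRecord], intact_alleles: set[str]
) -> int:
    """Count of mutations with at least one binding peptide (eluted ligand
    rank <= 0.5, inclusive) against at least one intact allele."""
    counted: set[str] = set()
    for rec in records:
        if rec.allele in intact_alleles and rec.binder:
            counted.add(rec.mutation_id)
    return len(counted)


def total_neoantigen_burden(records: Iterable[NeoantigenRecord]) -> int:
    """Mutations binding any of the patient's alleles, intact or not."""
    return len({r.mutation_id for r in records if r.binder})


def read_neoantigen_table(path) -> list[NeoantigenRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        NeoantigenRecord(
            mutation_id=str(r.mutation_id),
            peptide=str(r.peptide),
            allele=str(r.allele),
            eluted_ligand_rank=float(r.rank),
        )
        for r in df.itertuples()
    ]


def classify_heterogeneity(presence_by_region: Mapping[str, bool]) -> str | None:
    """'ubiquitous' if a disruption event is present in every evaluable
    primary region, 'heterogeneous' otherwise; None for single-region
    tumors, where the distinction is undefined."""
    if len(presence_by_region) < 2:
        return None
    return "ubiquitous" if all(presence_by_region.values()) else "heterogeneous"


def detect_convergence(
    mechanism_regions: Mapping[str, set[str]],
) -> tuple[bool, tuple[str, ...]]:
    """Convergent disruption of one allele across regions.

    ``mechanism_regions`` maps mechanism name -> set of regions where that
    mechanism disrupts the allele.  The allele is convergent when two
    distinct mechanisms act on it in entirely separate regions — i.e. some
    mechanism pair has non-empty, disjoint region sets.  Returns the flag
    and the sorted mechanism combination involved.
    """
    active = {m: r for m, r in mechanism_regions.items() if r}
    names = sorted(active)
    combo: set[str] = set()
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            if active[m1].isdisjoint(active[m2]):
                combo.update((m1, m2))
    return (bool(combo), tuple(sorted(combo)))


def danaher_cd8(tpm_cd8a: float, tpm_cd8b: float, epsilon: float = LOG2_EPSILON) -> float:
    """Danaher CD8 T cell score: mean log2 TPM of CD8A and CD8B.

    A small pseudocount keeps zero TPMs finite.
    """
    if tpm_cd8a < 0 or tpm_cd8b < 0:
        raise ValueError("TPMs must be non-negative")
    return (math.log2(tpm_cd8a + epsilon) + math.log2(tpm_cd8b + epsilon)) / 2


def region_summary_frame(summaries: Sequence[RegionDisruptionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        triple = s.intact_counts or (None, None, None)
        rows.append(
            {
                "patient_id": s.patient_id,
                "region": s.region,
                "evaluable": s.evaluable,
                "intact_none": triple[0],
                "intact_after_loh": triple[1],
                "intact_after_loh_repression": triple[2],
                "reasons": ";".join(s.reasons),
            }
        )
    return pd.DataFrame(rows)
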