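"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results through simple enumeration or string
manipulation, sharing no code path with the library implementation.
"""

from __future__ import annotations

from hladisrupt.reference import AlleleModel

STOPS = ("TAA", "TAG", "TGA")


def classify_junction_oracle(interval: tuple[int, int], model: AlleleModel) -> str:
    """Rule-by-rule junction classification.

    canonical: the interval is exactly an intron.  excluded: it overlaps the
    first or last exon.  complete skip: donor-to-acceptor interval containing
    a whole exon.  partial skip / retention: exactly one annotated boundary,
    the other strictly inside an exon / intron.  Otherwise unclassified.
    """
    s, e = interval
    exons = model.exons
    introns = model.introns
    if any((s, e) == (f.start, f.end) for f in introns):
        return "canonical"
    for terminal in (exons[0], exons[-1]):
        if s < terminal.end and e > terminal.start:
            return "excluded"
    donors = {f.start for f in introns}
    acceptors = {f.end for f in introns}
    if s in donors and e in acceptors:
        if any(s <= f.start and f.end <= e for f in exons):
            return "complete_exon_skip"
    annotated = donors | acceptors
    if (s in annotated) != (e in annotated):
        inner = e if s in annotated else s
        if any(f.start < inner < f.end for f in exons):
            return "partial_exon_skip"
        if any(f.start < inner < f.end for f in introns):
            return "partial_intron_retention"
    return "unclassified"


def modified_transcript_oracle(
    model: AlleleModel, kind: str, start: int, end: int
) -> str:
    """Mature transcript after a skip/retain change, by direct masking."""
    keep = [False] * len(model.sequence)
    for f in model.exons:
        for p in range(f.start, f.end):
            keep[p] = True
    for p in range(start, end):
        keep[p] = kind == "retain"
    return "".join(
        model.sequence[p]
        for p in range(len(model.sequence))
        if keep[p] and p >= model.cds_start
    )


def first_stop_codon_index(transcript: str) -> int | None:
    for i in range(0, len(transcript) - 2, 3):
        if transcript[i : i + 3] in STOPS:
            return i
    return None


def ptc_oracle(model: AlleleModel, kind: str, start: int, end: int) -> bool:
    """Codon-scan PTC check: does translation of the modified transcript
    stop strictly before the canonical stop codon's position?"""
    canonical = "".join(
        model.sequence[p]
        for f in model.exons
        for p in range(f.start, f.end)
        if p >= model.cds_start
    )
    canon_stop = first_stop_codon_index(canonical)
    if canon_stop is None:
        return False
    # genomic position of the canonical stop codon's first base
    exonic_positions = [
        p for f in model.exons for p in range(f.start, f.end) if p >= model.cds_start
    ]
    stop_genomic = exonic_positions[canon_stop]
    modified = modified_transcript_oracle(model, kind, start, end)
    # offset of that genomic base within the modified transcript
    kept = set(exonic_positions)
    if kind == "skip":
        kept -= set(range(start, end))
    else:
        kept |= {p for p in range(start, end) if p >= model.cds_start}
    offset = sum(1 for p in kept if p < stop_genomic)
    new_stop = first_stop_codon_index(modified)
    return new_stop is not None and new_stop < offset
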