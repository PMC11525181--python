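"""Shared fixtures: toy allele database, a spec-like 4-exon allele, and a
SAM-writing helper for alignment-level tests."""

from __future__ import annotations

import random

import pysam
import pytest

from hladisrupt.reference import AlleleModel, Feature
from hladisrupt.simulate import make_toy_allele_db


@pytest.fixture(scope="session")
def toy_db():
    db, _ = make_toy_allele_db(seed=7)
    return db


@pytest.fixture(scope="session")
def allele_a(toy_db):
    return toy_db["A*01:01"]


@pytest.fixture(scope="session")
def allele_a2(toy_db):
    return toy_db["A*02:01"]


@pytest.fixture(scope="session")
def four_exon_allele():
    """A 4-exon allele with round-number feature boundaries:
    exons [0,100) [200,300) [400,500) [600,700), introns between."""
    rng = random.Random(13)
    seq = "".join(rng.choice("ACGT") for _ in range(700))
    features = [
        Feature("exon", 1, 0, 100),
        Feature("intron", 1, 100, 200),
        Feature("exon", 2, 200, 300),
        Feature("intron", 2, 300, 400),
        Feature("exon", 3, 400, 500),
        Feature("intron", 3, 500, 600),
        Feature("exon", 4, 600, 700),
    ]
    return AlleleModel(
        allele_name="A*99:01", gene="HLA-A", sequence=seq, features=features
    )


def write_sam(path, references, reads):
    """Write a SAM file.

    ``references`` is a list of (name, length); ``reads`` a list of dicts
    with keys name, flag, ref (name or None), pos, cigar, seq and optional
    tags (list of (tag, value)).
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in references],
        }
    )
    ref_ids = {n: i for i, (n, _) in enumerate(references)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for spec in reads:
            read = pysam.AlignedSegment(header)
            read.query_name = spec["name"]
            read.flag = spec.get("flag", 0)
            if spec.get("ref") is not None:
                read.reference_id = ref_ids[spec["ref"]]
                read.reference_start = spec.get("pos", 0)
                read.cigarstring = spec.get("cigar")
                read.mapping_quality = spec.get("mapq", 60)
            seq = spec.get("seq")
            if seq:
                read.query_sequence = seq
                read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            for tag, value in spec.get("tags", []):
                read.set_tag(tag, value)
            out.write(read)
    return path


@pytest.fixture
def sam_writer():
    return write_sam
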