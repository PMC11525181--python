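"""Splice module: junction extraction, classification, novel transcript
proportion, consequences, enrichment testing and cohort filters."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy.stats import hypergeom

from hladisrupt import splice
from hladisrupt.reference import SpliceModification
from hladisrupt.simulate import make_toy_allele_db, simulate_rna_reads

from _oracles import classify_junction_oracle, ptc_oracle


class TestExtractJunctions:
    def _spliced_read(self, name, pos, cigar, seq_len=100, nh=1):
        return {
            "name": name, "flag": 0, "ref": "A*99:01", "pos": pos,
            "cigar": cigar, "seq": "A" * seq_len,
            "tags": [("NH", nh), ("NM", 0)],
        }

    def test_single_junction_counted(self, tmp_path, sam_writer, four_exon_allele):
        reads = [self._spliced_read(f"r{i}", 50, "50M100N50M") for i in range(5)]
        sam = sam_writer(tmp_path / "j.sam", [("A*99:01", 700)], reads)
        out = splice.extract_junctions(sam, "s")
        assert len(out) == 1
        assert out[0].interval == (100, 200)
        assert out[0].unique_reads == 5

    def test_read_with_two_gaps_increments_both(self, tmp_path, sam_writer):
        reads = [self._spliced_read("r0", 50, "50M100N100M100N50M", seq_len=200)]
        sam = sam_writer(tmp_path / "j2.sam", [("A*99:01", 700)], reads)
        out = splice.extract_junctions(sam, "s")
        assert {j.interval for j in out} == {(100, 200), (300, 400)}
        assert all(j.unique_reads == 1 for j in out)

    def test_multimapping_reads_ignored(self, tmp_path, sam_writer):
        reads = [
            self._spliced_read("u", 50, "50M100N50M", nh=1),
            self._spliced_read("m", 50, "50M100N50M", nh=3),
        ]
        sam = sam_writer(tmp_path / "j3.sam", [("A*99:01", 700)], reads)
        out = splice.extract_junctions(sam, "s")
        assert out[0].unique_reads == 1

    def test_counts_match_cigar_reparse(self, tmp_path, sam_writer):
        """Brute-force CIGAR re-parse on a random 40-read fixture."""
        rng = random.Random(23)
        reads = []
        for i in range(40):
            pos = rng.randrange(0, 80)
            gap = rng.choice([100, 150, 200])
            reads.append(self._spliced_read(f"r{i}", pos, f"60M{gap}N40M"))
        sam = sam_writer(tmp_path / "j4.sam", [("A*99:01", 1000)], reads)
        out = {j.interval: j.unique_reads for j in splice.extract_junctions(sam, "s")}
        brute: dict[tuple[int, int], int] = {}
        with pysam.AlignmentFile(str(sam), "r") as af:
            for read in af.fetch(until_eof=True):
                pos = read.reference_start
                for op, ln in read.cigartuples:
                    if op in (0, 2, 7, 8):
                        pos += ln
                    elif op == 3:
                        brute[(pos, pos + ln)] = brute.get((pos, pos + ln), 0) + 1
                        pos += ln
        assert out == brute


class TestClassifyJunction:
    @pytest.mark.parametrize(
        "interval,category",
        [
            ((100, 200), "canonical"),
            ((300, 400), "canonical"),
            ((100, 400), "complete_exon_skip"),  # whole exon 2
            ((100, 600), "complete_exon_skip"),  # exons 2 and 3
            ((100, 150), "partial_intron_retention"),  # retains [150, 200)
            ((150, 200), "partial_intron_retention"),  # retains [100, 150)
            ((100, 250), "partial_exon_skip"),  # loses [200, 250) of exon 2
            ((250, 300), "partial_exon_skip"),
            ((50, 200), "excluded"),  # reaches into exon 1
            ((500, 650), "excluded"),  # reaches into last exon
            ((120, 180), "unclassified"),  # both ends inside intron 1
            ((210, 290), "unclassified"),  # both ends inside exon 2
            ((200, 300), "unclassified"),  # exact exon interval, wrong polarity
        ],
    )
    def test_rule_examples(self, four_exon_allele, interval, category):
        assert splice.classify_junction(interval, four_exon_allele).category == category

    def test_affected_features(self, four_exon_allele):
        cls = splice.classify_junction((100, 400), four_exon_allele)
        assert cls.affected == (("exon", 2),)
        cls = splice.classify_junction((100, 150), four_exon_allele)
        assert cls.affected == (("intron", 1),)

    def test_outside_gene_body_rejected(self, four_exon_allele):
        with pytest.raises(ValueError):
            splice.classify_junction((650, 800), four_exon_allele)

    def test_matches_enumeration_oracle_sampled(self, four_exon_allele):
        """Spot-check the classifier against the rule-by-rule oracle on
        5,000 random ordered boundary pairs (exhaustive run lives in the
        acceptance suite)."""
        rng = random.Random(29)
        for _ in range(5000):
            s = rng.randrange(0, 699)
            e = rng.randrange(s + 1, 701)
            assert (
                splice.classify_junction((s, e), four_exon_allele).category
                == classify_junction_oracle((s, e), four_exon_allele)
            )


class TestCompleteIntronRetention:
    def test_supported_retention_detected(self, four_exon_allele):
        # intron 1 spans [100, 200)
        reads = (
            [(75, 125)] * 8  # cross the 5' boundary by >= 10 both sides
            + [(175, 225)] * 8  # cross the 3' boundary
            + [(110, 190)] * 3  # fill the middle
        )
        events = splice.detect_complete_intron_retention(reads, four_exon_allele)
        assert events == [(1, 8)]

    def test_zero_coverage_base_blocks_call(self, four_exon_allele):
        reads = [(75, 125)] * 8 + [(175, 225)] * 8  # hole in [125, 175)
        assert splice.detect_complete_intron_retention(reads, four_exon_allele) == []

    def test_insufficient_boundary_span_blocks_call(self, four_exon_allele):
        reads = [(95, 205)] * 1 + [(100, 200)] * 20  # only 1 true spanning read
        events = splice.detect_complete_intron_retention(reads, four_exon_allele)
        assert events == []  # [100,200) reads do not cross by min_span


class TestNovelTranscriptProportion:
    def test_simple_ratio(self):
        assert splice.novel_transcript_proportion(10, [90]) == pytest.approx(0.1)

    def test_zero_novel(self):
        assert splice.novel_transcript_proportion(0, [50]) == 0.0

    def test_exon_skip_averages_two_canonical_junctions(self):
        assert splice.novel_transcript_proportion(10, [80, 100]) == pytest.approx(0.1)

    def test_scale_invariance(self):
        p1 = splice.novel_transcript_proportion(7, [60, 80])
        p10 = splice.novel_transcript_proportion(70, [600, 800])
        assert p1 == pytest.approx(p10)

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            splice.novel_transcript_proportion(0, [0, 0])

    def test_overlapping_canonical_lookup(self, four_exon_allele):
        assert splice.overlapping_canonical_junctions((100, 400), four_exon_allele) == [
            (100, 200),
            (300, 400),
        ]
        assert splice.overlapping_canonical_junctions((100, 150), four_exon_allele) == [
            (100, 200)
        ]


class TestConsequence:
    def test_whole_exon_skip_inframe(self, allele_a):
        # exon lengths are 99, a codon multiple
        i1, i2 = allele_a.introns[0], allele_a.introns[1]
        consequence, _ = splice.splice_consequence(
            "complete_exon_skip", (i1.start, i2.end), allele_a
        )
        assert consequence == "inframe"

    def test_fifty_base_retention_frameshift(self, allele_a):
        i1 = allele_a.introns[0]
        consequence, _ = splice.splice_consequence(
            "partial_intron_retention", (i1.start, i1.start + 50), allele_a
        )
        assert consequence == "frameshift"

    def test_ptc_matches_codon_scan_oracle(self):
        """PTC flag against an independent string-level codon scan across
        random alleles and random partial events."""
        rng = random.Random(37)
        checked = 0
        for seed in range(5):
            db, _ = make_toy_allele_db(seed=100 + seed)
            for model in list(db.values())[:4]:
                for _ in range(5):
                    intron = rng.choice(model.introns)
                    cut = rng.randrange(intron.start + 1, intron.end)
                    interval = (intron.start, cut)
                    consequence, ptc = splice.splice_consequence(
                        "partial_intron_retention", interval, model
                    )
                    retained = splice.retained_interval(interval, model)
                    assert ptc == ptc_oracle(model, "retain", *retained)
                    expected_frame = (
                        "inframe" if (retained[1] - retained[0]) % 3 == 0 else "frameshift"
                    )
                    assert consequence == expected_frame
                    checked += 1
        assert checked == 100

    def test_start_lost_reported(self, allele_a):
        # a partial skip removing the start codon region
        interval = (allele_a.exons[0].start, allele_a.exons[0].start + 10)
        with pytest.raises(ValueError):
            # terminal-exon events are excluded upstream; consequence caller
            # still guards against unknown categories
            splice.splice_consequence("canonical", interval, allele_a)
        consequence, ptc = splice.splice_consequence(
            "partial_exon_skip", interval, allele_a
        )
        assert consequence == "start_lost"


class TestEnrichment:
    def test_tumor_enriched(self):
        p = splice.enrichment_test(30, 70, 0, 100)
        call = splice.enrichment_call(30 / 100, 0.0, p)
        assert call == "tumor_enriched"

    def test_identical_proportions_neither(self):
        p = splice.enrichment_test(10, 90, 10, 90)
        assert splice.enrichment_call(0.1, 0.1, p) == "neither"

    def test_tumor_depleted_by_symmetry(self):
        p = splice.enrichment_test(0, 100, 30, 70)
        assert splice.enrichment_call(0.0, 0.3, p) == "tumor_depleted"

    def test_pvalue_matches_hypergeometric(self):
        """Two-sided Fisher p as the sum of hypergeometric probabilities no
        larger than the observed table's."""
        a, b, c, d = 30, 70, 0, 100
        n_row1, n_col1, total = a + b, a + c, a + b + c + d
        rv = hypergeom(total, n_col1, n_row1)
        p_obs = rv.pmf(a)
        expected = sum(
            rv.pmf(k)
            for k in range(max(0, n_row1 + n_col1 - total), min(n_row1, n_col1) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert splice.enrichment_test(a, b, c, d) == pytest.approx(expected, rel=1e-6)

    def test_all_zero_table(self):
        assert splice.enrichment_test(0, 0, 0, 0) == 1.0


class TestPurityScaling:
    def test_plug_in(self):
        assert splice.purity_scaled_proportion(0.1, 0.5) == pytest.approx(0.2)

    def test_cap_at_one(self):
        assert splice.purity_scaled_proportion(0.6, 0.5) == 1.0

    def test_identity_at_full_purity(self):
        assert splice.purity_scaled_proportion(0.37, 1.0) == pytest.approx(0.37)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            splice.purity_scaled_proportion(0.1, 0.0)


class TestCohortFilters:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id", "sample_id", "allele", "start", "end",
                "unique_reads", "enrichment",
            ],
        )

    def test_normal_mode_kept_with_strong_other_sample(self):
        df = self._frame(
            [
                ["p1", "sA", "A*01:01", 100, 400, 2, "na"],
                ["p1", "sB", "A*01:01", 100, 400, 25, "na"],
            ]
        )
        kept = splice.junction_cohort_filters(df, "normal_cohort")
        # sA has >= 2 focal reads and sB provides the >= 20-read support;
        # sB itself has no other >= 20-read sample, so only sA is kept
        assert set(kept.sample_id) == {"sA"}

    def test_normal_mode_dropped_without_20_read_support(self):
        df = self._frame(
            [
                ["p1", "sA", "A*01:01", 100, 400, 2, "na"],
                ["p1", "sB", "A*01:01", 100, 400, 19, "na"],
            ]
        )
        kept = splice.junction_cohort_filters(df, "normal_cohort")
        # sA lacks a >= 20-read sample elsewhere; sB itself has >= 2 reads
        # and sA gives it no >= 20-read partner either
        assert kept.empty

    def test_tumor_mode_requires_enrichment_and_depth(self):
        df = self._frame(
            [
                ["p1", "r1", "A*01:01", 100, 400, 21, "tumor_enriched"],
                ["p1", "r2", "A*01:01", 100, 150, 21, "neither"],
                ["p1", "r3", "A*01:01", 300, 350, 5, "tumor_depleted"],
            ]
        )
        kept = splice.junction_cohort_filters(df, "tumor_cohort")
        assert list(kept.sample_id) == ["r1"]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            splice.junction_cohort_filters(self._frame([]), "nope")


class TestEndToEnd:
    def test_exon_skip_detected_and_enriched(self, tmp_path, toy_db):
        model = toy_db["A*01:01"]
        i1, i2 = model.introns[0], model.introns[1]
        mod = SpliceModification("skip", i1.start, i2.end)
        tumor_sam = tmp_path / "tumor.sam"
        normal_sam = tmp_path / "normal.sam"
        simulate_rna_reads(model, tumor_sam, mod, splice_proportion=0.3,
                           depth=150, seed=41)
        simulate_rna_reads(model, normal_sam, mod, splice_proportion=0.0,
                           depth=150, seed=42)
        tum = splice.extract_junctions(tumor_sam, "tumor")
        norm = splice.extract_junctions(normal_sam, "normal")
        events = splice.call_splice_events(tum, model, norm, rho=0.5)
        skips = [e for e in events if e.category == "complete_exon_skip"]
        assert len(skips) == 1
        ev = skips[0]
        assert ev.interval == (i1.start, i2.end)
        assert ev.enrichment == "tumor_enriched"
        assert abs(ev.novel_transcript_proportion - 0.3) <= 0.1
        assert ev.purity_scaled_proportion == pytest.approx(
            min(1.0, ev.novel_transcript_proportion / 0.5)
        )
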