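"""Junction extraction, event classification percentages, alleles and FPKM."""

import pysam
import pytest

from splicevar.genome_model import Transcript
from splicevar.rna_quant import (
    EventClassification,
    JunctionCount,
    RnaQuantError,
    allele_support,
    boundary_spanning_count,
    canonical_junction,
    classify_splice_event,
    exon_model_length,
    fpkm,
    junctions_from_alignments,
    percentile_rank,
)
from splicevar.somatic_caller import SomaticVariant
from splicevar.splice_annotator import SpliceAnnotation


def sam_record(name, pos, cigar, seq=None, contig="c1", contig_len=100000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": contig_len}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = pos - 1
    rec.cigarstring = cigar
    length = sum(n for op, n in rec.cigartuples if op in (0, 1, 4, 7, 8))
    rec.query_sequence = seq if seq is not None else "A" * length
    rec.mapping_quality = 60
    return rec


class TestJunctionsFromAlignments:
    def test_single_n_operation(self):
        (j,) = junctions_from_alignments([sam_record("r1", 1, "20M100N20M")])
        assert (j.donor_end, j.acceptor_start, j.read_count) == (20, 121, 1)

    def test_counts_aggregate(self):
        recs = [sam_record(f"r{i}", 1, "20M100N20M") for i in range(2)]
        (j,) = junctions_from_alignments(recs)
        assert j.read_count == 2

    def test_unspliced_read_yields_nothing(self):
        assert junctions_from_alignments([sam_record("r1", 1, "40M")]) == []

    def test_two_gaps_yield_two_junctions(self):
        js = junctions_from_alignments([sam_record("r1", 1, "10M50N10M50N10M")])
        assert [(j.donor_end, j.acceptor_start) for j in js] == [(10, 61), (70, 121)]


class TestBoundarySpanning:
    def test_continuous_reads_counted(self):
        recs = [sam_record(f"r{i}", 95, "10M") for i in range(5)]  # covers 95-104
        count, _ = boundary_spanning_count(recs, "c1", 99, min_anchor=5)
        assert count == 5

    def test_spliced_at_boundary_not_counted(self):
        rec = sam_record("r1", 81, "20M100N20M")  # N starts right after 100
        count, _ = boundary_spanning_count([rec], "c1", 100, min_anchor=6)
        assert count == 0

    def test_anchor_longer_than_overhang_not_counted(self):
        rec = sam_record("r1", 95, "10M")  # only 4 bases right of boundary 100
        count, _ = boundary_spanning_count([rec], "c1", 100, min_anchor=6)
        assert count == 0

    def test_query_alleles_extracted(self):
        rec = sam_record("r1", 95, "10M", seq="AAAAACAAAA")  # base C at pos 100
        _, alleles = boundary_spanning_count([rec], "c1", 99, min_anchor=5,
                                             query_position=100)
        assert alleles == ["C"]


@pytest.fixture()
def six_exon_transcript():
    exons = [(1 + i * 200, 100 + i * 200) for i in range(6)]  # 100 bp exons
    return Transcript("t6", "g", "c1", "+", exons, 1, exons[-1][1])


def annotation(transcript, side, exon_index, offset, pos, ref="G", alt="A"):
    v = SomaticVariant(transcript.contig, pos, ref, alt, 50, 25, 50, 40, 0, 0)
    return SpliceAnnotation(v, transcript.transcript_id, "splicing", side, offset,
                            None, exon_index=exon_index)


class TestClassifySpliceEvent:
    def test_exon_skip_percentages(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 5, 1, t.exon_by_index(5)[1] + 1)
        junctions = [
            JunctionCount("c1", *canonical_junction(t, 4), 3),   # ex4-ex5
            JunctionCount("c1", *canonical_junction(t, 5), 5),   # ex5-ex6
            JunctionCount("c1", t.exon_by_index(4)[1], t.exon_by_index(6)[0], 28),
        ]
        ev = classify_splice_event(ann, junctions, t)
        assert ev.status == "ok"
        assert ev.percent_by_kind == {"wild_type": 22, "exon_skip": 78}
        skip = next(o for o in ev.outcomes if o.kind == "exon_skip")
        assert skip.detail == "skip_exon_5" and skip.read_count == 28

    def test_retention_percentages(self, six_exon_transcript):
        t = six_exon_transcript
        boundary = t.exon_by_index(5)[0]
        ann = annotation(t, "acceptor", 5, -1, boundary - 1)
        junctions = [JunctionCount("c1", *canonical_junction(t, 4), 7)]
        ev = classify_splice_event(ann, junctions, t, spanning_count=5)
        assert ev.percent_by_kind == {"wild_type": 58, "intron_retention": 42}

    def test_cryptic_site_three_way_split(self, six_exon_transcript):
        t = six_exon_transcript
        boundary = t.exon_by_index(5)[0]
        ann = annotation(t, "acceptor", 5, -1, boundary - 1)
        junctions = [
            JunctionCount("c1", *canonical_junction(t, 4), 58),
            JunctionCount("c1", t.exon_by_index(4)[1], boundary + 5, 5),
        ]
        ev = classify_splice_event(ann, junctions, t, spanning_count=37)
        assert ev.percent_by_kind == {
            "wild_type": 58, "intron_retention": 37, "cryptic": 5,
        }
        cryptic = next(o for o in ev.outcomes if o.kind == "cryptic")
        assert cryptic.detail == "cryptic_shift_+5"

    def test_only_canonical_reads_pure_wild_type(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 3, 1, t.exon_by_index(3)[1] + 1)
        junctions = [JunctionCount("c1", *canonical_junction(t, 3), 12)]
        ev = classify_splice_event(ann, junctions, t)
        assert ev.percent_by_kind == {"wild_type": 100}

    def test_zero_informative_reads_flagged_not_expressed(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 3, 1, t.exon_by_index(3)[1] + 1)
        ev = classify_splice_event(ann, [], t)
        assert ev == EventClassification([], "not_expressed")

    def test_unrelated_junctions_ignored(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 5, 1, t.exon_by_index(5)[1] + 1)
        junctions = [
            JunctionCount("c1", *canonical_junction(t, 5), 10),
            JunctionCount("c1", *canonical_junction(t, 1), 99),  # far from event
        ]
        ev = classify_splice_event(ann, junctions, t)
        assert ev.percent_by_kind == {"wild_type": 100}
        assert sum(o.read_count for o in ev.outcomes) == 10

    def test_percentages_sum_to_100_within_rounding(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 5, 1, t.exon_by_index(5)[1] + 1)
        for counts in [(28, 5, 3), (1, 1, 1), (7, 11, 13), (100, 1, 0)]:
            junctions = [
                JunctionCount("c1", *canonical_junction(t, 4), counts[1]),
                JunctionCount("c1", t.exon_by_index(4)[1], t.exon_by_index(6)[0],
                              counts[0]),
            ]
            ev = classify_splice_event(ann, junctions, t, spanning_count=counts[2])
            assert abs(sum(o.percent for o in ev.outcomes) - 100) <= 1

    def test_invariant_to_junction_order(self, six_exon_transcript):
        t = six_exon_transcript
        ann = annotation(t, "donor", 5, 1, t.exon_by_index(5)[1] + 1)
        junctions = [
            JunctionCount("c1", *canonical_junction(t, 4), 3),
            JunctionCount("c1", *canonical_junction(t, 5), 5),
            JunctionCount("c1", t.exon_by_index(4)[1], t.exon_by_index(6)[0], 28),
        ]
        a = classify_splice_event(ann, junctions, t)
        b = classify_splice_event(ann, junctions[::-1], t)
        assert a == b


class TestAlleleSupport:
    def variant(self):
        return SomaticVariant("c1", 100, "G", "A", 50, 25, 50, 40, 0, 0)

    def test_all_mutant_is_exclusive(self):
        s = allele_support(["A"] * 5, self.variant())
        assert (s.mut_count, s.wt_count, s.exclusive_mutant) == (5, 0, True)

    def test_mixed_alleles_not_exclusive(self):
        s = allele_support(["A", "A", "A", "G", "G"], self.variant())
        assert (s.mut_count, s.wt_count, s.exclusive_mutant) == (3, 2, False)

    def test_no_reads_not_exclusive(self):
        s = allele_support([], self.variant())
        assert (s.mut_count, s.wt_count, s.exclusive_mutant) == (0, 0, False)


class TestFpkm:
    def test_unit_case(self):
        assert fpkm(1000, 1000, 1_000_000) == pytest.approx(1000.0)

    def test_arithmetic_case(self):
        assert fpkm(2843, 2160, 40_000_000) == pytest.approx(32.905, abs=5e-3)

    def test_zero_fragments_zero_fpkm(self):
        assert fpkm(0, 14087, 10_000_000) == 0.0

    def test_linearity(self):
        base = fpkm(500, 2000, 10_000_000)
        assert fpkm(1000, 2000, 10_000_000) == pytest.approx(2 * base)
        assert fpkm(500, 4000, 10_000_000) == pytest.approx(base / 2)
        assert fpkm(500, 2000, 20_000_000) == pytest.approx(base / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(RnaQuantError):
            fpkm(10, 0, 1_000_000)
        with pytest.raises(RnaQuantError):
            fpkm(10, 1000, 0)


class TestPercentileRank:
    def test_maximum_is_100(self):
        assert percentile_rank(10, list(range(1, 11))) == 100

    def test_unique_minimum(self):
        assert percentile_rank(1, list(range(1, 11))) == 10

    def test_ninety(self):
        assert percentile_rank(9, list(range(1, 11))) == 90

    def test_empty_dataset_rejected(self):
        with pytest.raises(RnaQuantError):
            percentile_rank(1, [])


def test_exon_model_length(six_exon_transcript):
    assert exon_model_length(six_exon_transcript) == 600
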