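"""Coordinate conventions, GTF/BED round-trips and interval primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncforge.genomic_model import (
    BedParseError,
    GenomicInterval,
    GtfParseError,
    TranscriptModel,
    interval_overlap,
    read_bed_segmentation,
    read_gtf,
    transcript_length,
    write_gtf,
)


def _gtf(tmp_path, text):
    p = tmp_path / "in.gtf"
    p.write_text(text)
    return p


class TestGtfReader:
    def test_one_based_inclusive_converted_to_half_open(self, tmp_path):
        p = _gtf(tmp_path, 'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        (t,) = read_gtf(p)
        assert t.exons[0] == GenomicInterval("chr1", 100, 200, "+")

    def test_out_of_order_exons_are_sorted_into_one_transcript(self, tmp_path):
        p = _gtf(
            tmp_path,
            'chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        )
        (t,) = read_gtf(p)
        assert [e.start for e in t.exons] == [100, 500]

    def test_zero_start_is_a_parse_error_with_line_number(self, tmp_path):
        p = _gtf(tmp_path, 'chr1\tsrc\texon\t0\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(GtfParseError, match=":1:"):
            read_gtf(p)

    def test_end_before_start_rejected(self, tmp_path):
        p = _gtf(tmp_path, 'chr1\tsrc\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(GtfParseError, match="rejected record"):
            read_gtf(p)

    def test_malformed_line_names_its_number(self, tmp_path):
        p = _gtf(
            tmp_path,
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "chr1 not a gtf line\n",
        )
        with pytest.raises(GtfParseError, match=":2:"):
            read_gtf(p)

    def test_read_write_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        transcripts = []
        for i in range(20):
            start = int(rng.integers(0, 5000))
            a = int(rng.integers(50, 300))
            gap = int(rng.integers(10, 200))
            b = int(rng.integers(50, 300))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                TranscriptModel(
                    f"t{i}", f"g{i}",
                    (
                        GenomicInterval("chr2", start, start + a, strand),
                        GenomicInterval("chr2", start + a + gap, start + a + gap + b, strand),
                    ),
                )
            )
        p1 = tmp_path / "a.gtf"
        p2 = tmp_path / "b.gtf"
        write_gtf(transcripts, p1)
        again = read_gtf(p1)
        write_gtf(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for orig, back in zip(transcripts, again):
            assert orig.exons == back.exons
            assert (orig.transcript_id, orig.gene_id) == (back.transcript_id, back.gene_id)


class TestTranscriptLength:
    @pytest.mark.parametrize(
        "exons, expected",
        [
            ([(100, 400)], 300),
            ([(0, 100), (200, 350)], 250),  # exonic, not the 350 bp span
            ([(0, 201)], 201),
            ([(0, 200)], 200),
        ],
    )
    def test_mature_length_is_sum_of_exons(self, exons, expected):
        t = TranscriptModel(
            "t", "g", tuple(GenomicInterval("chr1", s, e, "+") for s, e in exons)
        )
        assert transcript_length(t) == expected

    def test_length_filter_boundary_is_strict(self, params):
        passing = TranscriptModel("t1", "g1", (GenomicInterval("chr1", 0, 201, "+"),))
        failing = TranscriptModel("t2", "g2", (GenomicInterval("chr1", 0, 200, "+"),))
        assert transcript_length(passing) > params.min_length_bp
        assert not transcript_length(failing) > params.min_length_bp


class TestTranscriptModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            TranscriptModel(
                "t", "g",
                (GenomicInterval("chr1", 0, 500, "+"), GenomicInterval("chr1", 400, 900, "+")),
            )

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="one chromosome"):
            TranscriptModel(
                "t", "g",
                (GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr2", 200, 300, "+")),
            )


class TestBedSegmentation:
    def test_single_segment(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t0\t1000\tHeterch\n")
        seg = read_bed_segmentation(p, "NB")
        assert list(seg.segments("chr1")) == [(0, 1000, "Heterch")]

    def test_overlapping_segments_error(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t0\t500\tActProm\nchr1\t400\t900\tHeterch\n")
        with pytest.raises(BedParseError, match="overlap"):
            read_bed_segmentation(p, "NB")

    def test_unknown_state_label_error(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t0\t1000\tQuies\n")
        with pytest.raises(BedParseError, match="Quies"):
            read_bed_segmentation(p, "NB")


class TestIntervalOverlap:
    def test_matches_per_base_membership_on_random_intervals(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a0, b0 = sorted(rng.integers(0, 10_000, size=2) + [0, 1])
            a1, b1 = sorted(rng.integers(0, 10_000, size=2) + [0, 1])
            ia = GenomicInterval("chr1", int(a0), int(b0))
            ib = GenomicInterval("chr1", int(a1), int(b1))
            brute = len(set(range(ia.start, ia.end)) & set(range(ib.start, ib.end)))
            assert interval_overlap(ia, ib) == brute

    def test_cross_chromosome_overlap_is_zero(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr2", 0, 100)
        assert interval_overlap(a, b) == 0

    @settings(derandomize=True, max_examples=200)
    @given(
        a0=st.integers(0, 9_999), alen=st.integers(1, 2_000),
        b0=st.integers(0, 9_999), blen=st.integers(1, 2_000),
    )
    def test_overlap_is_symmetric_bounded_and_exact_on_self(self, a0, alen, b0, blen):
        a = GenomicInterval("chr1", a0, a0 + alen)
        b = GenomicInterval("chr1", b0, b0 + blen)
        ov = interval_overlap(a, b)
        assert ov == interval_overlap(b, a)
        assert 0 <= ov <= min(len(a), len(b))
        assert interval_overlap(a, a) == len(a)
        if ov:  # shared bases imply the spans actually intersect
            assert a.start < b.end and b.start < a.end
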