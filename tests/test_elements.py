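"""Element detection: quality segmentation, motif/poly/vector scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estclean.elements import (ReadRecord, classify_context,
                               collect_element_hits, find_motif_hits,
                               find_poly_tail, find_vector_hits,
                               segment_quality)
from estclean.protocol import random_dna, reverse_complement

dna = st.text(alphabet="ACGT", min_size=30, max_size=300)


def brute_force_motif_scan(bases: str, motif: str, max_mm: int):
    k = len(motif)
    return [
        (i, i + k)
        for i in range(len(bases) - k + 1)
        if sum(a != b for a, b in zip(bases[i : i + k], motif)) <= max_mm
    ]


class TestSegmentQuality:
    def test_uniform_high_read_is_one_segment(self):
        read = ReadRecord("r", "A" * 500, np.full(500, 40))
        segs = segment_quality(read)
        assert [(s.start, s.end, s.label) for s in segs] == [(0, 500, "high")]

    def test_read_without_quals_is_all_high(self):
        segs = segment_quality(ReadRecord("r", "ACGT" * 50))
        assert [(s.start, s.end, s.label) for s in segs] == [(0, 200, "high")]

    def test_high_then_low_split_at_boundary(self):
        # 300 bases of Q40 followed by 200 of Q5: frozen against per-window
        # means with window 20 / threshold Q16
        quals = np.concatenate([np.full(300, 40), np.full(200, 5)])
        segs = segment_quality(ReadRecord("r", "A" * 500, quals))
        assert [(s.start, s.end, s.label) for s in segs] == \
            [(0, 300, "high"), (300, 500, "low")]

    def test_qual_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            ReadRecord("r", "ACGT", np.array([40, 40]))

    @given(st.lists(st.integers(0, 60), min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_segments_partition_read(self, quals):
        read = ReadRecord("r", "A" * len(quals), np.array(quals))
        segs = segment_quality(read)
        assert segs[0].start == 0 and segs[-1].end == len(quals)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start        # contiguous, no overlap
            assert a.label != b.label      # merging is idempotent


class TestFindMotifHits:
    def test_exact_hit(self):
        hits = find_motif_hits("TTGAATTCAA", "GAATTC")
        assert [(h.start, h.end, h.mismatches) for h in hits] == [(2, 8, 0)]

    def test_one_mismatch_fraction(self):
        target = "TT" + "GGCACGTGG" + "AA"  # one substituted base
        (hit,) = find_motif_hits(target, "GGCACGAGG", max_mismatch=1)
        assert hit.mismatches == 1
        assert hit.matched_fraction == pytest.approx(8 / 9)

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            find_motif_hits("ACGT", "")

    @given(dna, st.sampled_from(["GAATTC", "CTCGAG", "GGCACGAGG"]),
           st.integers(0, 2))
    @settings(max_examples=150, deadline=None)
    def test_equals_brute_force_hamming_scan(self, bases, motif, max_mm):
        hits = find_motif_hits(bases, motif, max_mm)
        assert [(h.start, h.end) for h in hits] == \
            brute_force_motif_scan(bases, motif, max_mm)


class TestFindPolyTail:
    @pytest.mark.parametrize("bases,expected", [
        ("CCAAAAAAAAGG", [(2, 10)]),
        ("AAAAAAA", []),                      # 7 < min length 8
        ("C" * 5 + "A" * 12 + "C" * 5, [(5, 17)]),
    ])
    def test_simple_runs(self, bases, expected):
        hits = find_poly_tail(bases, "A")
        assert [(h.start, h.end) for h in hits] == expected

    def test_interior_impurity_extends_run(self):
        # 12 A with one interior G: a single 13-base run (1/13 <= 10%)
        bases = "CC" + "A" * 6 + "G" + "A" * 6 + "CC"
        (hit,) = find_poly_tail(bases, "A")
        assert (hit.start, hit.end, hit.mismatches) == (2, 15, 1)

    def test_multiple_disjoint_tails_reported(self):
        bases = "A" * 10 + "CGTCGTCGCG" + "A" * 9
        hits = find_poly_tail(bases, "A")
        assert [(h.start, h.end) for h in hits] == [(0, 10), (20, 29)]


class TestFindVectorHits:
    def test_exact_planted_fragment(self, protocol):
        frag = protocol.vector_sequence[1000:1060]
        read = "ACGTT" * 10 + frag + "TGCAA" * 10
        hits = find_vector_hits(read, protocol.vector_sequence)
        assert any(
            h.start <= 50 and h.end >= 110 and h.strand_form == "sense"
            and h.matched_fraction == 1.0 for h in hits
        )

    def test_reverse_complement_fragment_is_antisense(self, protocol):
        frag = reverse_complement(protocol.vector_sequence[1000:1060])
        read = "ACGTT" * 10 + frag + "TGCAA" * 10
        hits = find_vector_hits(read, protocol.vector_sequence)
        (hit,) = [h for h in hits if h.end - h.start >= 60]
        assert hit.strand_form == "antisense"
        vs, ve = hit.vector_interval
        assert vs <= 1000 and ve >= 1060  # covers the planted fragment
        assert ve - vs <= 62              # no spurious over-extension

    def test_no_hits_in_vector_free_reads(self, protocol):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            read = random_dna(500, rng, scrub=False)
            assert find_vector_hits(read, protocol.vector_sequence) == []

    def test_strand_symmetry(self, protocol):
        rng = np.random.default_rng(7)
        frag = protocol.vector_sequence[400:480]
        read = random_dna(100, rng) + frag + random_dna(100, rng)
        fwd = find_vector_hits(read, protocol.vector_sequence)
        rev = find_vector_hits(reverse_complement(read),
                               protocol.vector_sequence)
        n = len(read)
        mirrored = sorted((n - h.end, n - h.start) for h in rev)
        assert sorted(h.interval for h in fwd) == mirrored


class TestClassifyContext:
    def _segments(self, n, low_from=None):
        read = ReadRecord(
            "r", "A" * n,
            None if low_from is None else np.concatenate(
                [np.full(low_from, 40), np.full(n - low_from, 5)]
            ),
        )
        return segment_quality(read)

    def test_vector_in_high_quality_is_hv(self, protocol):
        from estclean.elements import ElementHit
        vh = [ElementHit("vector", 100, 200)]
        assert classify_context((120, 180), vh, self._segments(300)) == "HV"

    def test_nonvector_low_quality_is_ln(self):
        assert classify_context((250, 290), [], self._segments(300, 200)) == "LN"

    def test_majority_rules_give_lv(self):
        # 60% vector coverage, 40% high quality -> vector + low = LV
        from estclean.elements import ElementHit
        vh = [ElementHit("vector", 0, 60)]
        segs = self._segments(100, 40)
        assert classify_context((0, 100), vh, segs) == "LV"


def test_collected_hits_are_sorted_and_labelled(protocol):
    frag = protocol.vf2_sequence
    read = ReadRecord("r.b1", reverse_complement(frag) + "C" + "T" * 18
                      + "ACGTC" * 60)
    scan = collect_element_hits(read, protocol)
    labels = [h.label for h in scan.motif_hits]
    assert "VF2'" in labels and "polyT" in labels
    starts = [h.start for h in scan.motif_hits]
    assert starts == sorted(starts)
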