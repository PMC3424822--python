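"""RECA/DBT/CASE classification and the DBT motif scanner."""

import numpy as np
import pytest

from estclean.abnormality import (DBT_TYPE1_MOTIF, DBT_TYPE2_MOTIF,
                                  classify_read, detect_dbt)
from estclean.elements import ReadRecord
from estclean.pipeline import process_read
from estclean.protocol import random_dna, reverse_complement
from estclean.simulate import LAYOUTS, ConstructRecipe, make_construct

from conftest import analyze


def naive_dbt_scan(bases, max_mm=2):
    """Independent left-to-right non-overlapping Hamming scan oracle."""
    k = len(DBT_TYPE1_MOTIF)
    out = []
    i = 0
    while i + k <= len(bases):
        window = bases[i : i + k]
        mm1 = sum(a != b for a, b in zip(window, DBT_TYPE1_MOTIF))
        mm2 = sum(a != b for a, b in zip(window, DBT_TYPE2_MOTIF))
        if min(mm1, mm2) <= max_mm:
            out.append((i, i + k, 1 if mm1 <= mm2 else 2))
            i += k
        else:
            i += 1
    return out


class TestDetectDBT:
    def test_type1_motif_is_its_own_reverse_complement(self):
        assert reverse_complement(DBT_TYPE1_MOTIF) == DBT_TYPE1_MOTIF

    @pytest.mark.parametrize("motif,dbt_type", [
        (DBT_TYPE1_MOTIF, 1), (DBT_TYPE2_MOTIF, 2),
    ])
    def test_single_planted_motif(self, motif, dbt_type, rng):
        bases = random_dna(200, rng) + motif + random_dna(200, rng)
        (hit,) = detect_dbt(bases)
        assert (hit.start, hit.end, hit.dbt_type) == (200, 224, dbt_type)

    def test_reverse_complement_maps_type1_to_type1(self, rng):
        bases = random_dna(150, rng) + DBT_TYPE1_MOTIF + random_dna(150, rng)
        fwd = detect_dbt(bases)
        rev = detect_dbt(reverse_complement(bases))
        assert [h.dbt_type for h in fwd] == [h.dbt_type for h in rev] == [1]

    def test_triple_repetition_indexing(self, rng):
        bases = (random_dna(100, rng) + DBT_TYPE1_MOTIF * 3
                 + random_dna(100, rng))
        hits = detect_dbt(bases)
        assert [h.repetition_index for h in hits] == [1, 2, 3]

    def test_matches_naive_scan_on_random_reads_with_planted_motifs(self):
        rng = np.random.default_rng(99)
        for i in range(2000):
            bases = random_dna(150, rng, scrub=False)
            if i % 3 == 0:
                p = int(rng.integers(0, 120))
                motif = (DBT_TYPE1_MOTIF, DBT_TYPE2_MOTIF)[i % 2]
                bases = bases[:p] + motif + bases[p:]
            got = [(h.start, h.end, h.dbt_type) for h in detect_dbt(bases)]
            assert got == naive_dbt_scan(bases)


class TestClassification:
    def _pattern(self, protocol, layout, seed=21):
        rng = np.random.default_rng(seed)
        recipe = ConstructRecipe(layout, "t", 400)
        bases, truth = make_construct(recipe, protocol, rng)
        read = ReadRecord("t", bases, None, truth.direction)
        scan, _, pattern = analyze(read, protocol)
        return scan, pattern, truth

    @pytest.mark.parametrize("layout", [l for l in LAYOUTS
                                        if l.startswith("RECA")])
    def test_reca_layouts_round_trip_both_directions(self, protocol, layout):
        scan, pattern, truth = self._pattern(protocol, layout)
        primary, _ = classify_read(pattern, truth.direction, [],
                                   scan.vector_hits, protocol)
        assert primary is not None
        assert primary.category == truth.expected_category

    def test_reca_calls_are_exclusive(self, protocol):
        """A single-layout read never matches two RECA templates."""
        from estclean.abnormality import RECA_SIGNATURES, classify_reca
        for layout in (l for l in LAYOUTS if l.startswith("RECA")):
            scan, pattern, truth = self._pattern(protocol, layout)
            rendering = pattern.render()
            matches = [
                cat for cat, tpl in RECA_SIGNATURES.items()
                if tpl.get(truth.direction) == rendering
            ]
            assert len(matches) == 1

    def test_expected_layout_not_classified(self, protocol):
        scan, pattern, truth = self._pattern(protocol, "expected-5")
        primary, secondary = classify_read(pattern, "5", [],
                                           scan.vector_hits, protocol)
        assert primary is None and secondary == []

    @pytest.mark.parametrize("layout", ["CASE-1", "CASE-2", "CASE-3", "CASE-4",
                                        "CASE-5", "CASE-6", "CASE-7", "CASE-8"])
    def test_case_layouts_round_trip(self, protocol, layout):
        scan, pattern, truth = self._pattern(protocol, layout)
        primary, _ = classify_read(pattern, truth.direction, [],
                                   scan.vector_hits, protocol)
        assert primary is not None and primary.category == layout

    def test_case5_is_also_a_direction_conflict(self, protocol):
        scan, pattern, _ = self._pattern(protocol, "CASE-5")
        primary, secondary = classify_read(pattern, "5", [],
                                           scan.vector_hits, protocol)
        assert primary.category == "CASE-5"
        assert [c.category for c in secondary] == ["direction-conflict"]

    def test_normal_5prime_read_is_not_a_conflict(self, protocol):
        scan, pattern, _ = self._pattern(protocol, "expected-5")
        from estclean.abnormality import detect_direction_conflict
        assert detect_direction_conflict(pattern, "5") is None

    def test_reca_takes_precedence_over_conflict(self, protocol):
        # a 3' RECA-B1 read carries only sense-strand-family termini plus a
        # 3TNS variant; RECA wins, no separate conflict call
        scan, pattern, truth = self._pattern(protocol, "RECA-B1-3")
        primary, secondary = classify_read(pattern, "3", [],
                                           scan.vector_hits, protocol)
        assert primary.category == "RECA-B1"
        assert "direction-conflict" not in [c.category for c in secondary]


class TestResolveDBT:
    def test_internal_dbt_in_3prime_pair_is_trimmable(self, protocol):
        rng = np.random.default_rng(8)
        bases, truth = make_construct(
            ConstructRecipe("DBT-internal", "t.b1", 400), protocol, rng
        )
        rep = process_read(ReadRecord("t.b1", bases, None, "3"), protocol)
        assert rep.primary_category == "DBT-internal"
        assert rep.outcome == "clean"
        assert rep.clean_interval == truth.clean_interval

    @pytest.mark.parametrize("layout", ["DBT1-chimera", "DBT2-chimera"])
    def test_unflanked_dbt_is_chimeric(self, protocol, layout):
        rng = np.random.default_rng(8)
        bases, _ = make_construct(ConstructRecipe(layout, "t.g1", 400),
                                  protocol, rng)
        rep = process_read(ReadRecord("t.g1", bases, None, "5"), protocol)
        assert rep.primary_category == "DBT-chimera"
        assert rep.outcome == "filtered"

    def test_repetition_run_grouped_into_one_call(self, protocol, rng):
        bases = (random_dna(250, rng) + DBT_TYPE1_MOTIF * 3
                 + random_dna(250, rng))
        rep = process_read(ReadRecord("t.g1", bases, None, "5"), protocol)
        assert rep.primary_category == "DBT-chimera"
        assert len(rep.primary.evidence) == 3
        assert [h.repetition_index for h in rep.dbt_hits] == [1, 2, 3]
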