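"""Terminus assembly, confidence scoring, pattern strings and pair selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estclean.elements import ReadRecord
from estclean.patterns import (TerminusHit, assemble_termini, build_pattern,
                               context_score, disambiguate,
                               find_reasonable_pairs, score_terminus,
                               select_best_pair)
from estclean.protocol import mirror_name, random_dna, reverse_complement
from estclean.simulate import ConstructRecipe, make_construct

from conftest import analyze


def _read(protocol, *pieces, rng_seed=5, direction="5"):
    """Concatenate named protocol pieces and random inserts into a read."""
    from estclean.simulate import _segments

    seg = _segments(protocol)
    rng = np.random.default_rng(rng_seed)
    parts = []
    for p in pieces:
        if isinstance(p, int):
            parts.append(random_dna(p, rng))
        else:
            parts.append(seg[p])
    return ReadRecord("t.g1" if direction == "5" else "t.b1",
                      "".join(parts), None, direction)


class TestAssembly:
    def test_full_3tss_locus_yields_canonical_after_disambiguation(self, protocol):
        read = _read(protocol, 300, "3TSS")
        _, termini, _ = analyze(read, protocol)
        assert [t.def_name for t in termini] == ["3TSS"]
        assert termini[0].n_elements == 3

    def test_vf2_c_polyt_assembles_5tns4(self, protocol):
        read = _read(protocol, "5TNS-4", 300, direction="3")
        _, termini, _ = analyze(read, protocol)
        assert [t.def_name for t in termini] == ["5TNS-4"]

    def test_bare_enzyme_site_is_not_a_terminus(self, protocol):
        rng = np.random.default_rng(11)
        read = ReadRecord("t.g1", random_dna(150, rng) + "CTCGAG"
                          + random_dna(150, rng), None, "5")
        _, termini, _ = analyze(read, protocol)
        assert termini == []


class TestScoring:
    def _hit(self, name, family, n_elem, span=60, mism=0):
        return TerminusHit(name, family, 0, span, [], n_elem, mism)

    def test_perfect_canonical_terminus_scores_100(self, protocol):
        tdef = protocol.termini["5TNS"]
        h = score_terminus(self._hit("5TNS", "5TNS", 3), tdef, 3, "HV", "HN")
        assert (h.a_score, h.b_score, h.c_score) == (100.0, 100.0, 100.0)
        assert h.confidence == pytest.approx(100.0)

    def test_completeness_ordering_within_family(self, protocol):
        scores = {}
        for name in ("5TNS", "5TNS-1", "5TNS-2", "5TNS-3"):
            tdef = protocol.termini[name]
            h = score_terminus(
                self._hit(name, "5TNS", len(tdef.elements)), tdef, 3,
                "HV", "HN",
            )
            scores[name] = h.a_score
        assert scores["5TNS"] > scores["5TNS-1"] == scores["5TNS-2"] \
            > scores["5TNS-3"]

    def test_context_score_contract(self):
        # vector expected upstream: vector=100, low-quality N=50, high-quality N=0
        assert context_score("HV", "vector") == 100.0
        assert context_score("LV", "vector") == 100.0
        assert context_score("LN", "vector") == 50.0
        assert context_score("HN", "vector") == 0.0

    def test_partial_terminus_confidence_arithmetic(self, protocol):
        # 2/3 elements (66.67), both flanks low-quality non-vector (b=50),
        # perfect bases (c=100), equal weights -> 72.22
        tdef = protocol.termini["5TNS-1"]
        h = score_terminus(self._hit("5TNS-1", "5TNS", 2), tdef, 3, "LN", "LN")
        assert h.confidence == pytest.approx(72.22, abs=0.01)

    def test_invalid_weights_rejected(self, protocol):
        tdef = protocol.termini["5TNS"]
        with pytest.raises(ValueError):
            score_terminus(self._hit("5TNS", "5TNS", 3), tdef, 3, "HV", "HN",
                           weights=(0.5, 0.5, 0.5))

    @given(st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)))
    @settings(max_examples=20, deadline=None)
    def test_confidence_is_linear_in_weights(self, protocol, raw):
        w = np.array(raw) / sum(raw)
        tdef = protocol.termini["5TNS-2"]
        h = score_terminus(self._hit("5TNS-2", "5TNS", 2, span=56, mism=3),
                           tdef, 3, "LN", "HN", tuple(w))
        expected = w[0] * h.a_score + w[1] * h.b_score + w[2] * h.c_score
        assert h.confidence == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= h.confidence <= 100.0


class TestDisambiguate:
    def _scored(self, name, family, start, end, conf, a=50.0, c=100.0):
        h = TerminusHit(name, family, start, end, [], 2, 0)
        h.confidence, h.a_score, h.c_score = conf, a, c
        return h

    def test_higher_confidence_wins_overlap(self):
        full = self._scored("3TNS", "3TNS", 10, 75, 95.0, a=100, c=100)
        sub = self._scored("3TNS-5", "3TNS", 25, 75, 60.0, a=33, c=40)
        assert disambiguate([sub, full]) == [full]

    def test_disjoint_hits_unchanged(self):
        a = self._scored("5TSS", "5TSS", 0, 65, 90.0)
        b = self._scored("3TSS", "3TSS", 400, 474, 88.0)
        assert disambiguate([b, a]) == [a, b]

    def test_exact_tie_keeps_earlier_start_deterministically(self):
        a = self._scored("3TNS-1", "3TNS", 100, 115, 72.0)
        b = self._scored("5TSS-1", "5TSS", 109, 124, 72.0)
        for order in ([a, b], [b, a]):
            assert disambiguate(list(order)) == [a]


class TestBuildPattern:
    def test_lone_poly_fragments_pattern(self, protocol):
        read = _read(protocol, 150, "3TSS-3", 150, "3TSS-3", 150)
        _, _, pattern = analyze(read, protocol)
        assert pattern.render() == "N,3TSS-3,N,3TSS-3,N"

    def test_5tns4_leading_pattern(self, protocol):
        read = _read(protocol, "5TNS-4", 300, direction="3")
        _, _, pattern = analyze(read, protocol)
        assert pattern.render() == "5TNS-4,N"

    def test_read_with_no_hits_is_single_n(self, protocol):
        rng = np.random.default_rng(3)
        read = ReadRecord("t.g1", random_dna(400, rng), None, "5")
        _, _, pattern = analyze(read, protocol)
        assert pattern.render() == "N"

    def test_reverse_complement_mirrors_pattern(self, protocol):
        rng = np.random.default_rng(17)
        recipe = ConstructRecipe("expected-5", "t.g1", 400)
        bases, _ = make_construct(recipe, protocol, rng)
        fwd = ReadRecord("t.g1", bases, None, "5")
        rev = ReadRecord("t.b1", reverse_complement(bases), None, "3")
        _, _, pf = analyze(fwd, protocol)
        _, _, pr = analyze(rev, protocol)

        def mirror(tok):
            return tok if tok in "NV" else mirror_name(tok)

        assert pr.tokens == [mirror(t) for t in reversed(pf.tokens)]

    def test_overlapping_termini_rejected(self, protocol):
        a = TerminusHit("3TSS", "3TSS", 10, 80, [], 3, 0)
        b = TerminusHit("3TSS-1", "3TSS", 50, 90, [], 2, 0)
        with pytest.raises(ValueError):
            build_pattern(ReadRecord("t", "A" * 100), [a, b], [], [])


class TestPairs:
    def _t(self, family, start, end, conf=90.0):
        h = TerminusHit(family, family, start, end, [], 3, 0)
        h.confidence = conf
        return h

    def test_pair_separation_and_membership(self):
        left = self._t("5TSS", 10, 75)
        right = self._t("3TSS", 600, 680)
        res = find_reasonable_pairs([left, right], "5")
        assert len(res.pairs) == 1
        assert res.pairs[0].separation == 525

    def test_short_separation_excluded(self):
        left = self._t("5TSS", 10, 75)
        right = self._t("3TSS", 225, 300)  # separation 150
        assert find_reasonable_pairs([left, right], "5").pairs == []

    def test_order_violation_gives_no_pair(self):
        tns3 = self._t("3TNS", 0, 65)
        tns5 = self._t("5TNS", 400, 474)
        assert find_reasonable_pairs([tns3, tns5], "3").pairs == []

    def test_unknown_direction_warns(self):
        res = find_reasonable_pairs([self._t("5TSS", 0, 65)], "unknown")
        assert res.pairs == [] and res.warning is not None

    def test_boundary_at_exactly_200(self):
        left = self._t("5TNS", 0, 74)
        right199 = self._t("3TNS", 273, 340)
        right200 = self._t("3TNS", 274, 340)
        assert find_reasonable_pairs([left, right199], "3").pairs == []
        assert len(find_reasonable_pairs([left, right200], "3").pairs) == 1

    def test_best_pair_matches_exhaustive_search(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            termini = []
            pos = 0
            for _ in range(int(rng.integers(2, 6))):
                start = pos + int(rng.integers(0, 300))
                end = start + int(rng.integers(20, 80))
                fam = ["5TSS", "3TSS"][int(rng.integers(2))]
                termini.append(self._t(fam, start, end,
                                       float(rng.integers(30, 101))))
                pos = end
            res = find_reasonable_pairs(termini, "5")
            best = select_best_pair(res.pairs)
            brute = [
                (l, r) for l in termini for r in termini
                if l.family == "5TSS" and r.family == "3TSS"
                and r.start - l.end >= 200
            ]
            if not brute:
                assert best is None
                continue
            expected = max(
                brute,
                key=lambda p: (p[0].confidence + p[1].confidence,
                               p[1].start - p[0].end, -p[0].start),
            )
            assert (best.left, best.right) == expected

    def test_empty_input_selects_none(self):
        assert select_best_pair([]) is None
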