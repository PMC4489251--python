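"""Search engine: decomposition, bidirectional matching, merging, scoring."""

import math

import numpy as np
import pytest

from affixpat.affix import build_affix_array
from affixpat.esa import normalize_seq
from affixpat.fixtures import random_matrix, random_query, random_target
from affixpat.oracle import oracle_search
from affixpat.query import (
    Query,
    SeqElement,
    StructElement,
    default_pairing_matrix,
    pair_cost,
    parse_pairing_matrix,
    parse_query,
)
from affixpat.results import collapse_matches, element_layout
from affixpat.search import (
    bidirectional_search,
    decompose_query,
    search,
    specificity_rank,
)

from conftest import engine_keys, oracle_keys


def q_of(seq, struct):
    return parse_query(seq, struct)


class TestDecompose:
    def test_two_hairpins_with_linker(self):
        q = q_of("G" * 16, "((...))..((...))")
        sections, remainder = decompose_query(q)
        assert [(s.start, s.end) for s in sections] == [(0, 6), (9, 15)]
        assert remainder == [(7, 8)]

    def test_multiloop_outer_stem_goes_to_remainder(self):
        q = q_of("G" * 26, "(((..((...))..((...))..)))")
        sections, remainder = decompose_query(q)
        assert [(s.start, s.end) for s in sections] == [(5, 11), (14, 20)]
        assert remainder == [(0, 4), (12, 13), (21, 25)]

    def test_unpaired_query_has_no_sections(self):
        q = q_of("GGGGG", ".....")
        sections, remainder = decompose_query(q)
        assert sections == []
        assert remainder == [(0, 4)]

    def test_bulged_stem_stays_one_section(self):
        # interior dots do not break an unbranched stem
        q = q_of("G" * 12, "((.((...))))")
        sections, remainder = decompose_query(q)
        assert [(s.start, s.end) for s in sections] == [(0, 11)]
        assert remainder == []

    def test_sections_and_remainder_partition_query(self, rng):
        for _ in range(50):
            q = random_query(rng)
            sections, remainder = decompose_query(q)
            covered = set()
            for s in sections:
                covered |= set(range(s.start, s.end + 1))
            for a, b in remainder:
                covered |= set(range(a, b + 1))
            assert covered == set(range(len(q)))
            for s in sections:
                assert all(s.start <= i and j <= s.end for i, j in s.pairs)
                assert s.loop[0] > s.loop[1] or all(
                    q.struct[k].kind in ("dot", "gap")
                    for k in range(s.loop[0], s.loop[1] + 1)
                )


class TestSpecificity:
    def test_concrete_section_scores_zero(self):
        q = q_of("GGAAACC", "((...))")
        (sec,), _ = decompose_query(q)
        assert specificity_rank(sec, q) == 0

    def test_wildcards_count(self):
        q = q_of("GGNNNCC", "((...))")
        (sec,), _ = decompose_query(q)
        assert specificity_rank(sec, q) == 3

    def test_most_specific_section_searched_first(self):
        from affixpat.search import _section_order

        q = q_of("GGAAACCAAGGNNNCC", "((...))..((...))")
        sections, _ = decompose_query(q)
        order = _section_order(sections, q)
        assert [sections[i].start for i in order] == [0, 9]


class TestBidirectionalSearch:
    def test_single_hairpin_exact(self, default_matrix):
        q = q_of("GGAAACC", "((...))")
        (sec,), _ = decompose_query(q)
        afx = build_affix_array("UGGAAACCU")
        [m] = bidirectional_search(afx, sec, q, default_matrix)
        assert (m.start, m.end, m.gaps, m.cost) == (1, 8, (), 0.0)

    def test_gapped_stem(self, default_matrix):
        q = q_of("GG[2]CC", "(([2]))")
        (sec,), _ = decompose_query(q)
        afx = build_affix_array("GGACC")
        [m] = bidirectional_search(afx, sec, q, default_matrix)
        assert (m.start, m.end, m.cost) == (0, 5, 0.0)
        assert dict(m.gaps) == {2: 1}
        afx = build_affix_array("GGCC")
        [m] = bidirectional_search(afx, sec, q, default_matrix)
        assert (m.start, m.end) == (0, 4)
        assert dict(m.gaps) == {2: 0}

    def test_no_match_on_hostile_target(self, default_matrix):
        q = q_of("GGAAACC", "((...))")
        (sec,), _ = decompose_query(q)
        afx = build_affix_array("AAAAAAAA")
        assert bidirectional_search(afx, sec, q, default_matrix) == []

    def test_pair_cost_accumulates(self):
        matrix = parse_pairing_matrix(
            "A C G U\n"
            "A inf inf inf 0\n"
            "C inf inf 0 inf\n"
            "G inf 0 inf 1.5\n"
            "U 0 inf 1.5 inf\n"
        )
        q = q_of("GGAAANN", "((...))")
        (sec,), _ = decompose_query(q)
        afx = build_affix_array("GGAAAUC")  # G-U wobble inner, G-C outer
        [m] = bidirectional_search(afx, sec, q, matrix)
        assert m.cost == 1.5


class TestMergeAndRemainder:
    def test_fixed_linker_admits_exact_distance_only(self, default_matrix):
        q = q_of("GGAAACCAAGGAAACC", "((...))..((...))")
        hit = "GGAAACCAAGGAAACC"
        assert engine_keys("t", hit, q, default_matrix) == oracle_keys(
            "t", hit, q, default_matrix
        ) and len(engine_keys("t", hit, q, default_matrix)) == 1
        miss = "GGAAACCAAAGGAAACC"  # linker one nucleotide too long
        assert engine_keys("t", miss, q, default_matrix) == set()

    def test_gapped_linker_window(self, default_matrix):
        q = q_of("GGAAACCAA[2]GGAAACC", "((...))..[2]((...))")
        for extra in range(4):
            t = "GGAAACC" + "AA" + "U" * extra + "GGAAACC"
            got = engine_keys("t", t, q, default_matrix)
            want = oracle_keys("t", t, q, default_matrix)
            assert got == want
            assert bool(got) == (extra <= 2)

    def test_multiloop_closing_stem_checked_in_remainder(self, default_matrix):
        q = q_of("GCCAAAGGCCAAAGGC", "(((...))((...)))")
        t = "GCCAAAGGCCAAAGGC"
        assert engine_keys("t", t, q, default_matrix) == oracle_keys(
            "t", t, q, default_matrix
        )
        # break only the outer (remainder) pair: G...C -> G...A
        t_bad = t[:-1] + "A"
        assert engine_keys("t", t_bad, q, default_matrix) == set()

    def test_remainder_window_beyond_target_end_rejected(self, default_matrix):
        q = q_of("GGAAACCAAA", "((...))...")
        t = "GGAAACCA"  # hairpin fits, trailing remainder does not
        assert engine_keys("t", t, q, default_matrix) == set()


class TestSearchEndToEnd:
    def test_wildcard_stem_hairpin(self, default_matrix):
        q = q_of("NNNAAANNN", "(((...)))")
        ms = search([("t", "GGGAAACCCU")], q, default_matrix)
        assert len(ms) == 1
        m = ms[0]
        assert (m.start, m.end, m.cost) == (1, 9, 0.0)
        assert m.realized_struct == "(((...)))"
        assert m.matched_seq == "GGGAAACCC"

    def test_target_wildcard_defeats_query_n(self, default_matrix):
        q = q_of("NNNAAANNN", "(((...)))")
        assert search([("t", "GGNAAACCC")], q, default_matrix) == []

    def test_assignment_level_gap_counting(self, default_matrix):
        q = q_of("N[2]N", ".[2].")
        ms = search([("t", "AAAAA")], q, default_matrix)
        assert len(ms) == 9
        by_gap = {}
        for m in ms:
            by_gap.setdefault(m.gap_total, 0)
            by_gap[m.gap_total] += 1
        assert by_gap == {0: 4, 1: 3, 2: 2}

    def test_collapse_keeps_min_gap_total_per_span(self, default_matrix):
        q = q_of("N[2]N[2]N", ".[2].[2].")
        t = "AAAAAA"
        full = search([("t", t)], q, default_matrix)
        collapsed = search([("t", t)], q, default_matrix, collapse=True)
        assert collapsed == collapse_matches(full)
        spans = [(m.start, m.end) for m in collapsed]
        assert len(spans) == len(set(spans))
        for m in collapsed:
            rivals = [
                f for f in full if (f.start, f.end) == (m.start, m.end)
            ]
            best = min((f.gap_total, f.gap_lengths) for f in rivals)
            assert (m.gap_total, m.gap_lengths) == best

    def test_multi_record_union(self, default_matrix):
        q = q_of("GGAAACC", "((...))")
        ms = search(
            [("a", "GGAAACC"), ("b", "UUUU"), ("c", "AGGAAACCA")], q, default_matrix
        )
        assert [(m.target_id, m.start) for m in ms] == [("a", 1), ("c", 2)]

    def test_zero_hairpin_query_uses_forward_scan(self, default_matrix):
        q = q_of("ARG[1]U", "...[1].")
        t = "UAAGUUAGGUA"
        assert engine_keys("t", t, q, default_matrix) == oracle_keys(
            "t", t, q, default_matrix
        )


class TestProperties:
    def test_oracle_equivalence_randomized(self, rng, default_matrix):
        for trial in range(150):
            q = random_query(rng)
            t = random_target(rng, int(rng.integers(5, 200)))
            m = random_matrix(rng)
            assert engine_keys("t", t, q, m) == oracle_keys("t", t, q, m), trial

    def test_gap_monotonicity(self, rng, default_matrix):
        trials = 0
        while trials < 40:
            q = random_query(rng)
            if not q.gap_slots:
                continue
            trials += 1
            t = random_target(rng, int(rng.integers(20, 150)))
            base = engine_keys("t", t, q, default_matrix)
            slot = int(q.gap_slots[int(rng.integers(0, len(q.gap_slots)))])
            seq = list(q.seq)
            struct = list(q.struct)
            seq[slot] = SeqElement("gap", max_len=seq[slot].max_len + 1)
            struct[slot] = StructElement("gap", max_len=struct[slot].max_len + 1)
            from affixpat.query import make_query

            bigger = make_query(seq, struct)
            assert base <= engine_keys("t", t, bigger, default_matrix)

    def test_all_wildcard_window_count(self, default_matrix):
        t = "ACGUACGUACGUACGU"
        for k in (1, 3, 7):
            q = q_of("N" * k, "." * k)
            assert len(search([("t", t)], q, default_matrix)) == len(t) - k + 1

    def test_cost_additivity_recomputed_from_match_fields(self, rng):
        for _ in range(30):
            q = random_query(rng)
            if not q.pairs:
                continue
            t = random_target(rng, int(rng.integers(20, 150)))
            m = random_matrix(rng)
            for match in search([("t", t)], q, m):
                layout = element_layout(q, match.gap_lengths)
                total = 0.0
                for i, j in q.pairs:
                    c = pair_cost(
                        m,
                        match.matched_seq[layout[i][0]],
                        match.matched_seq[layout[j][0]],
                    )
                    assert math.isfinite(c)
                    total += c
                assert match.cost == pytest.approx(total)
                assert len(match.matched_seq) == len(match.realized_struct)
                assert len(match.matched_seq) == q.fixed_len + match.gap_total
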