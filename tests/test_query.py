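"""Query language, pairing matrices and matching predicates."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from affixpat.query import (
    IUPAC_EXPANSION,
    QueryError,
    default_pairing_matrix,
    iupac_matches,
    make_query,
    pair_cost,
    parse_pairing_matrix,
    parse_query,
    parse_sequence_pattern,
    parse_structure_pattern,
    render_sequence_pattern,
    render_structure_pattern,
)


class TestSequencePattern:
    def test_codes_and_gap_decomposition(self):
        els = parse_sequence_pattern("ANN[3]GG")
        kinds = [(e.kind, e.code, e.max_len) for e in els]
        assert kinds == [
            ("code", "A", 0),
            ("code", "N", 0),
            ("code", "N", 0),
            ("gap", None, 3),
            ("code", "G", 0),
            ("code", "G", 0),
        ]

    def test_t_is_u_and_case_insensitive(self):
        assert [e.code for e in parse_sequence_pattern("t")] == ["U"]
        assert [e.code for e in parse_sequence_pattern("acgtRy")] == list("ACGURY")

    @pytest.mark.parametrize(
        "text",
        ["A[x]G", "A[]G", "A[2G", "AZG", "", "A[10001]G"],
        ids=["nondigit", "empty-gap", "unclosed", "bad-char", "empty", "over-cap"],
    )
    def test_malformed_patterns_rejected(self, text):
        with pytest.raises(QueryError):
            parse_sequence_pattern(text)

    def test_error_names_offending_column(self):
        with pytest.raises(QueryError, match="column 2"):
            parse_sequence_pattern("A[x]G")


class TestStructurePattern:
    def test_tokenization(self):
        els = parse_structure_pattern("((.[2].))")
        assert [(e.kind, e.max_len) for e in els] == [
            ("open", 0), ("open", 0), ("dot", 0), ("gap", 2),
            ("dot", 0), ("close", 0), ("close", 0),
        ]

    @pytest.mark.parametrize("text", ["(.(", "())(", "", "(.[x].)"])
    def test_invalid_structures_rejected(self, text):
        with pytest.raises(QueryError):
            parse_structure_pattern(text)


class TestMakeQuery:
    def test_bracket_pairs_and_shared_gap(self):
        q = parse_query("GG[2]CC", "(([2]))")
        assert set(q.pairs) == {(0, 4), (1, 3)}
        assert q.gap_slots == (2,)
        assert q.fixed_len == 4
        assert q.max_span == 6

    def test_gap_bound_mismatch(self):
        with pytest.raises(QueryError, match="mismatch"):
            parse_query("GG[2]CC", "(([3]))")

    def test_gap_position_mismatch(self):
        with pytest.raises(QueryError):
            parse_query("G[2]GCC", "(([2]))")

    def test_length_mismatch(self):
        with pytest.raises(QueryError):
            parse_query("AAAA", "...")

    def test_unpaired_query_has_no_pairs(self):
        q = parse_query("AAA", "...")
        assert q.pairs == ()


class TestRenderRoundTrip:
    @given(
        st.lists(
            st.one_of(
                st.sampled_from(sorted(IUPAC_EXPANSION)),
                st.integers(0, 9).map(lambda k: f"[{k}]"),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_parse_render_parse_identity(self, parts):
        text = "".join(parts)
        els = parse_sequence_pattern(text)
        assert render_sequence_pattern(els) == text
        assert parse_sequence_pattern(render_sequence_pattern(els)) == els

    def test_structure_render_round_trip(self):
        text = "((.[2].))..[3]"
        els = parse_structure_pattern(text)
        assert render_structure_pattern(els) == text


class TestPairingMatrix:
    def test_default_allows_watson_crick_and_wobble_at_zero(self, default_matrix):
        for b1, b2 in ("AU", "UA", "CG", "GC", "GU", "UG"):
            assert pair_cost(default_matrix, b1, b2) == 0.0
        for b1, b2 in ("AA", "AC", "AG", "CA", "CC", "CU", "GA", "GG", "UC", "UU"):
            assert math.isinf(pair_cost(default_matrix, b1, b2))

    def test_parse_matrix_file(self):
        text = (
            "  A C G U\n"
            "A inf inf inf 0\n"
            "C inf inf 0 inf\n"
            "G inf 0 inf 1.0\n"
            "U 0 inf 1.0 inf\n"
        )
        m = parse_pairing_matrix(text)
        assert pair_cost(m, "G", "U") == 1.0
        assert pair_cost(m, "G", "C") == 0.0
        assert math.isinf(pair_cost(m, "A", "C"))

    @pytest.mark.parametrize(
        "text",
        [
            "A C G\nA 0 0 0\nC 0 0 0\nG 0 0 0",           # 3x3
            "A C G U\nA 0 0 0 0\nC 0 0 0 0\nG 0 0 0 0",    # missing row
            "A C G U\nA 0 0 0 -1\nC 0 0 0 0\nG 0 0 0 0\nU 0 0 0 0",  # negative
            "A C G X\nA 0 0 0 0\nC 0 0 0 0\nG 0 0 0 0\nU 0 0 0 0",   # bad label
            "",
        ],
    )
    def test_malformed_matrices_rejected(self, text):
        with pytest.raises(QueryError):
            parse_pairing_matrix(text)

    def test_all_infinite_matrix_rejected(self):
        rows = ["A C G U"] + [f"{b} inf inf inf inf" for b in "ACGU"]
        with pytest.raises(QueryError):
            parse_pairing_matrix("\n".join(rows))

    def test_wildcard_target_base_cannot_pair(self, default_matrix):
        assert math.isinf(pair_cost(default_matrix, "#", "U"))
        assert math.isinf(pair_cost(default_matrix, "G", "#"))


class TestIupacMatches:
    def test_purine_code(self):
        assert iupac_matches("R", "G")
        assert iupac_matches("R", "A")
        assert not iupac_matches("R", "U")

    def test_target_wildcard_matches_nothing(self):
        # an N in the *target* fails every query code, query N included
        assert not iupac_matches("N", "#")
        assert iupac_matches("N", "A")

    def test_expansion_table_against_biopython(self):
        # independent cross-check: Biopython's ambiguity table (DNA values,
        # T renamed to U)
        from Bio.Data.IUPACData import ambiguous_dna_values

        for code, bases in ambiguous_dna_values.items():
            if code == "X":
                continue
            rna_code = "U" if code == "T" else code
            expected = frozenset(bases.replace("T", "U"))
            assert IUPAC_EXPANSION[rna_code] == expected
            for b in "ACGU":
                assert iupac_matches(rna_code, b) == (b in expected)

    def test_invalid_code_raises(self):
        with pytest.raises(QueryError):
            iupac_matches("Z", "A")
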