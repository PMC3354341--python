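"""Dot-bracket parsing, language enumeration, motif decomposition."""

import pytest
from hypothesis import given, settings, strategies as st

from rnaunrank.structures import (
    MIN_HAIRPIN,
    SecondaryStructure,
    StructureError,
    decompose_motifs,
    enumerate_language,
    motif_instances,
    parse_dotbracket,
)


class TestParse:
    def test_minimal_structure(self):
        s = parse_dotbracket("(|||)")
        assert s.pairs == ((0, 4),)
        assert s.length == 5

    def test_dot_dialect_maps_to_bars(self):
        s = parse_dotbracket("..((...))", dialect="dot")
        assert s.word == "||((|||))"

    def test_auto_detects_dots(self):
        assert parse_dotbracket(".(...)").word == "|(|||)"

    @pytest.mark.parametrize("bad,fragment", [
        ("(||)", "hairpin"),
        ("(|||", "unmatched"),
        ("|||)", "unmatched"),
        ("|||||", "unpaired"),
        ("(|x|)", "foreign"),
        ("", "empty"),
    ])
    def test_invalid_words_are_rejected_with_reason(self, bad, fragment):
        with pytest.raises(StructureError, match=fragment):
            parse_dotbracket(bad)

    def test_mixed_dialects_rejected(self):
        with pytest.raises(StructureError):
            parse_dotbracket(".|(...)")

    def test_render_round_trip(self, language):
        for s in language[9]:
            assert parse_dotbracket(s.render("bar")).word == s.word
            assert parse_dotbracket(s.render("dot"), dialect="dot").word == s.word

    @settings(derandomize=True, max_examples=300)
    @given(st.text(alphabet="()|", max_size=14))
    def test_parser_agrees_with_membership_predicate(self, text):
        # a word parses iff it is balanced with hairpins >= 3 and >= 1 pair;
        # whenever it parses, rendering is the identity and the dot form of
        # the word converts back (dialect involution)
        try:
            s = parse_dotbracket(text)
        except StructureError:
            return
        assert s.word == text.strip()
        assert parse_dotbracket(s.render("dot"), dialect="dot").word == s.word
        assert all(j - i - 1 >= MIN_HAIRPIN or "(" in s.word[i + 1:j]
                   for i, j in s.pairs)


class TestEnumerate:
    def test_below_minimal_size(self):
        assert enumerate_language(4) == []

    def test_unique_minimal_word(self):
        assert [s.word for s in enumerate_language(5)] == ["(|||)"]

    def test_size_six(self):
        words = [s.word for s in enumerate_language(6)]
        assert sorted(words) == sorted(["(||||)", "|(|||)", "(|||)|"])
        assert words == sorted(words)  # lexicographic order

    def test_oracle_bound_guard(self):
        with pytest.raises(ValueError, match="bound"):
            enumerate_language(17)

    def test_all_members_validate(self, language):
        for n, structs in language.items():
            for s in structs:
                assert parse_dotbracket(s.word).word == s.word


# the printed worked example: a degree-3 multiloop whose branches contain a
# bulge-left helix, a degree-2 multiloop, and two interior loops
_HEL1 = "((((" "||||" "(((" "||||||" ")))" "))))"
_HEL21 = "((" "|" "(" "||||" ")" "))"
_HEL22 = "(" "|" "((" "|||||" "))" "|" ")"
_HEL2 = "(((" "||" "((((" "|" + _HEL21 + "|||||||" "))))" "|||||" + _HEL22 + ")))"
_HEL3 = "((" "||" "(" "||" "((((" "|||" "))))" "|||||||" ")" "||" "))"
EXAMPLE_WORD = "||||" "((((" "|||" + _HEL1 + "|||" + _HEL2 + "||" + _HEL3 + "|" "))))" "||"


class TestMotifs:
    def test_single_hairpin(self):
        p = decompose_motifs(parse_dotbracket("(|||)"))
        assert (p.num_h, p.num_bps, p.num_unp, p.num_hel, p.num_s, p.num_e) == \
            (1, 1, 3, 1, 0, 1)
        assert p.unp_h == 3

    def test_stacked_pair(self):
        p = decompose_motifs(parse_dotbracket("((|||))"))
        assert (p.num_s, p.num_h, p.num_hel, p.num_bps) == (1, 1, 1, 2)

    def test_worked_example_counts(self):
        p = decompose_motifs(parse_dotbracket(EXAMPLE_WORD))
        assert p.num_m == 2   # one degree-3, one degree-2 multiloop
        assert p.num_h == 4
        assert p.num_i == 4   # 2x7, 2x2, 1x7, 1x1
        assert p.num_b == 2   # bulge left of 4 and single bulge left

    def test_bulge_sides(self):
        left = decompose_motifs(parse_dotbracket("(||(|||))"))
        right = decompose_motifs(parse_dotbracket("((|||)||)"))
        assert left.num_b == right.num_b == 1
        assert left.unp_b == right.unp_b == 2

    def test_interior_loop(self):
        p = decompose_motifs(parse_dotbracket("(|(|||)||)"))
        assert p.num_i == 1 and p.unp_i == 3

    def test_unpaired_runs(self):
        p = decompose_motifs(parse_dotbracket("||(|||)|(||||)"))
        assert p.num_urs == 4

    def test_conservation_laws_exhaustive(self, language):
        for n in range(5, 13):
            for s in language[n]:
                p = decompose_motifs(s)
                assert p.num_e == 1
                assert p.num_unp == p.unp_e + p.unp_h + p.unp_b + p.unp_i + p.unp_m
                assert p.num_bps == p.num_s + p.num_h + p.num_b + p.num_i + p.num_m
                assert p.num_unp + 2 * p.num_bps == n
                assert p.bps_hel == p.num_bps
                m = motif_instances(s)
                assert len(m.helix_pairs) == p.num_hel
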