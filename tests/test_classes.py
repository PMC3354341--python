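"""Admissible specifications and exact class-size tables."""

import io

import pytest

from rnaunrank.classes import (
    Atomic,
    Product,
    Ref,
    SizeTable,
    UnionC,
    build_tables,
    grammar_to_spec,
)
from rnaunrank.training import chart_rule_counts


class TestGrammarToSpec:
    def test_root_union_inlines_chain_classes(self, star_integer):
        spec = grammar_to_spec(star_integer)
        root = spec.classes["S'"]
        assert isinstance(root, UnionC)
        # chain symbols E_{S,eps} / E_{A,S} collapse to the classes S and A
        assert root.parts == ((10000, Ref("E")), (212, Ref("S")), (3, Ref("A")))

    def test_products_are_binary_and_right_associated(self, star_integer):
        spec = grammar_to_spec(star_integer)
        f1 = spec.classes["F1"]  # the hairpin class for |||
        assert f1 == Product(Atomic("|"), Product(Atomic("|"), Atomic("|")))

    def test_duplicate_conclusion_classes_are_merged(self, star_integer):
        spec = grammar_to_spec(star_integer)
        # C -> C_{|,eps} |, D -> B_{|,eps} | and B -> B_{|,eps} | all inline
        # to the class Z| x Z|; only the first generates a named class
        barbar = Product(Atomic("|"), Atomic("|"))
        named = [k for k, v in spec.classes.items() if v == barbar]
        assert named == ["C2"]

    def test_rational_grammar_refused(self, star_rational):
        with pytest.raises(ValueError, match="integer"):
            grammar_to_spec(star_rational)


class TestSizeTable:
    def test_minimal_base_cases(self, weighted_table):
        assert weighted_table.size("C2", 2) == 1      # the class | x |
        assert weighted_table.size("C2", 3) == 0
        assert weighted_table.size("S'", 4) == 0

    def test_uniform_sizes_equal_language_counts(self, uniform_table, language):
        for n in range(1, 13):
            assert uniform_table.size("S'", n) == len(language[n])

    def test_weighted_sum_law(self, star_integer, weighted_table, language):
        # size(root, n) equals the sum of per-structure derivation weights
        for n in range(5, 11):
            total = 0
            for s in language[n]:
                w = 1
                for rid, c in chart_rule_counts(star_integer, s).items():
                    w *= int(star_integer.rule(rid).weight) ** c
                total += w
            assert weighted_table.size("S'", n) == total

    def test_ratio_law(self, star_integer, language):
        # pairwise weight ratios equal conditional-probability ratios, so a
        # common factor s*c^(n-1) links mu-weights and rounded probabilities
        from fractions import Fraction
        c = 10000
        for n in (6, 8):
            for s in language[n]:
                w = 1
                for rid, cnt in chart_rule_counts(star_integer, s).items():
                    w *= int(star_integer.rule(rid).weight) ** cnt
                lam = Fraction(w, 10000 * c ** (n - 1))
                assert 0 < lam < 1

    def test_positivity_of_all_admissible_sizes(self, weighted_table):
        weighted_table.ensure(120)
        assert all(weighted_table.size("S'", n) > 0 for n in range(5, 121))
        assert all(weighted_table.size("S'", n) == 0 for n in range(0, 5))

    def test_convolution_order_symmetry(self, weighted_table):
        # summing a product's split terms forwards or boustrophedon-style
        # gives the same total (the orders only permute the blocks)
        spec = weighted_table.spec
        expr = spec.classes["E1"]  # S x C
        for n in (8, 11, 14):
            seq = sum(weighted_table.size(expr.left, j)
                      * weighted_table.size(expr.right, n - j)
                      for j in range(n + 1))
            js = [j for k in range((n // 2) + 1) for j in {k, n - k}]
            bous = sum(weighted_table.size(expr.left, j)
                       * weighted_table.size(expr.right, n - j)
                       for j in sorted(set(js)))
            assert seq == bous == weighted_table.size(expr, n)

    def test_unknown_class(self, weighted_table):
        with pytest.raises(KeyError):
            weighted_table.size("nope", 5)


class TestPersistence:
    def test_save_load_round_trip(self, star_integer):
        spec = grammar_to_spec(star_integer)
        table = build_tables(spec, 25, fingerprint=star_integer.fingerprint())
        buf = io.StringIO()
        table.save(buf)
        buf.seek(0)
        again = SizeTable.load(buf, spec, fingerprint=star_integer.fingerprint())
        assert again.N == 25
        for n in range(26):
            assert again.size("S'", n) == table.size("S'", n)

    def test_stale_fingerprint_refused(self, star_integer):
        spec = grammar_to_spec(star_integer)
        table = build_tables(spec, 8, fingerprint="deadbeef00000000")
        buf = io.StringIO()
        table.save(buf)
        buf.seek(0)
        with pytest.raises(ValueError, match="rebuild"):
            SizeTable.load(buf, spec, fingerprint="0123456789abcdef")
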