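"""The five-step reweighting-normal-form transformation."""

from fractions import Fraction

import pytest

from rnaunrank.grammars import NT, Production, T, WeightedGrammar, load_builtin
from rnaunrank.reweight import round_half_away
from rnaunrank.rnf import collect_chains, to_rnf
from rnaunrank.structures import enumerate_language
from rnaunrank.training import chart_rule_counts
from rnaunrank import _tables


def word_weight(grammar, word):
    """Brute-force weight of a word: product of its derivation's rule weights."""
    class _W:
        pass
    w = _W()
    w.word = word
    counts = chart_rule_counts(grammar, w)
    out = Fraction(1)
    for rid, c in counts.items():
        out *= Fraction(grammar.rule(rid).weight) ** c
    return out


class TestCollectChains:
    def test_motif_grammar_has_32_chains(self, gsto):
        table = collect_chains(gsto)
        assert len(table) == 32
        assert set(table.targets) == {"E", "S", "T", "C", "L", "B", "H", "J",
                                      "K", "X", "Y", "Z", "N", "U"}

    def test_chain_weights_are_products(self, gsto):
        table = collect_chains(gsto)
        t_bar = next(c for c in table.targets["T"] if c.target.name == "|")
        assert t_bar.via == ("C",)
        assert t_bar.weight == gsto.rule(7).weight * gsto.rule(8).weight

    def test_chain_enumeration_order(self, gsto):
        # length first, terminal targets before nonterminal ones within a length
        table = collect_chains(gsto)
        assert [c.target.name for c in table.targets["T"]] == ["E", "C", "|", "S", "A"]
        assert [c.target.name for c in table.targets["N"]] == ["Z", "U", "|", "X", "A"]

    def test_small_grammar_chains(self):
        gd = load_builtin("Gd_eps_free")
        table = collect_chains(gd)
        got = [(c.source, c.target.name, c.via) for c in table.all_chains()]
        assert got == [("B", "C", ()), ("B", "|", ("C",)), ("C", "|", ())]

    def test_axiom_unit_rules_yield_no_chains(self):
        g = WeightedGrammar(["S", "A"], "S", [
            Production(1, "S", (NT("A"),), Fraction(1)),
            Production(2, "A", (T("("), T("|"), T("|"), T("|"), T(")")), Fraction(1)),
        ])
        assert len(collect_chains(g)) == 0

    def test_epsilon_grammar_refused(self):
        with pytest.raises(ValueError, match="epsilon"):
            collect_chains(load_builtin("Gd"))


@pytest.fixture(scope="module")
def report(gsto):
    return to_rnf(gsto)


class TestToRnfCensus:

    def test_step1_removes_22_unit_rules(self, report):
        assert len(report.removed_unit_rules) == 22

    def test_step1_gathers_32_chains(self, report):
        assert len(report.chains) == 32

    def test_step2_adds_32_chain_rules(self, report):
        assert len(report.chain_rules) == 32
        assert all(r.weight == 1 for r in report.chain_rules)

    def test_step3_yields_79_substituted_rules(self, report):
        assert len(report.substituted_rules) == 79

    def test_step4_removes_four_symbols_and_six_rules(self, report):
        assert report.dead_symbols == frozenset({"T", "L", "N", "Y"})
        assert len(report.dead_rules) == 6

    def test_result_has_73_main_plus_32_chain_rules(self, report):
        assert len(report.result.rules) == 105
        main = [r for r in report.result.rules[:73]]
        assert all(len(r.conclusion) > 1 or r.premise == "S'"
                   or r.weight == 1 for r in report.result.rules)
        assert len(main) == 73

    def test_result_matches_published_listing_rule_for_rule(self, report):
        for mine, (prem, concl) in zip(report.result.rules, _tables.GSTO_STAR_RULES):
            assert mine.premise == prem
            assert tuple(s.name for s in mine.conclusion) == tuple(concl.split())

    def test_rounded_weights_match_published_table(self, report):
        for i, r in enumerate(report.result.rules[:73]):
            expected = Fraction(_tables.TABLE5_WEIGHTS_E4[i], 10**4)
            assert round_half_away(r.weight, 4) == expected, r

    def test_chain_symbols_only_in_substituted_conclusions(self, report):
        chain_names = {c.symbol_name for c in report.chains.all_chains()}
        for r in report.result.rules[73:]:
            assert not any(s.name in chain_names for s in r.conclusion)


class TestToRnfSmallGrammar:
    def test_published_11_rule_result(self):
        report = to_rnf(load_builtin("Gd_eps_free"))
        listing = [(r.premise, " ".join(s.name for s in r.conclusion), r.weight)
                   for r in report.result.rules]
        assert listing == [
            ("S", "B", Fraction(1)),
            ("S", "B_{C,ε}", Fraction(1, 2)),
            ("S", "B_{|,C}", Fraction(1, 4)),
            ("B", "( B )", Fraction(1, 2)),
            ("B", "( B_{C,ε} )", Fraction(1, 4)),
            ("B", "( B_{|,C} )", Fraction(1, 8)),
            ("C", "| C", Fraction(1, 2)),
            ("C", "| C_{|,ε}", Fraction(1, 4)),
            ("B_{C,ε}", "C", Fraction(1)),
            ("B_{|,C}", "|", Fraction(1)),
            ("C_{|,ε}", "|", Fraction(1)),
        ]

    def test_chain_free_grammar_is_a_fixpoint(self):
        g = WeightedGrammar(["S", "B"], "S", [
            Production(1, "S", (NT("B"),), Fraction(1)),
            Production(2, "B", (T("("), NT("B"), T(")")), Fraction(1, 2)),
            Production(3, "B", (T("|"), T("|"), T("|")), Fraction(1, 2)),
        ])
        report = to_rnf(g)
        assert report.result.rules == g.rules
        assert not report.removed_unit_rules
        assert not report.chain_rules
        assert not report.dead_rules
        assert not report.axiom_fixes


class TestWordEquivalence:
    def test_weights_preserved_per_word(self, gsto, language):
        # the transformation changes the grammar, not the weighted language
        rnf_g = to_rnf(gsto).result
        for n in range(5, 10):
            for s in language[n]:
                assert word_weight(gsto, s.word) == word_weight(rnf_g, s.word)

    def test_json_report_serializes(self, gsto):
        payload = to_rnf(gsto).to_json()
        assert len(payload["chains"]) == 32
        assert len(payload["result"]["rules"]) == 105
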