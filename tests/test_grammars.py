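"""Grammar container, structural checks, and derivation counting."""

from fractions import Fraction

import pytest

from rnaunrank.grammars import (
    NT,
    Production,
    T,
    WeightedGrammar,
    check_consistency,
    check_epsilon_loop_free,
    count_derivations_by_length,
    load_builtin,
    verify_generating_function,
)


def make_grammar(rules, axiom="S", **kw):
    nts = []
    for r in rules:
        if r.premise not in nts:
            nts.append(r.premise)
    return WeightedGrammar(nts, axiom, rules, **kw)


class TestLoadBuiltin:
    def test_motif_grammar_shape(self, gsto):
        assert len(gsto.rules) == 54
        assert len(gsto.nonterminals) == 26
        assert gsto.axiom == "S'"
        assert gsto.stochastic

    def test_trained_probabilities_are_exact_rationals(self, gsto):
        assert gsto.weight_of("E", "S") == Fraction(137, 6476)
        assert gsto.weight_of("L", "A") == Fraction(605069, 792975)
        assert gsto.weight_of("M", "X Y") == 1  # the duplicated-label rule

    def test_simple_grammar(self):
        gs = load_builtin("Gs")
        assert len(gs.rules) == 7
        assert set(gs.nonterminals) == {"S", "A", "B", "C"}

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            load_builtin("nope")

    def test_referential_transparency(self):
        a, b = load_builtin("Gsto_hat"), load_builtin("Gsto_hat")
        assert a == b
        assert all(ra == rb for ra, rb in zip(a.rules, b.rules))

    def test_json_round_trip(self, star_rational):
        again = WeightedGrammar.from_json(star_rational.to_json())
        assert again == star_rational


class TestConsistency:
    def test_all_premises_sum_to_one(self, gsto):
        rep = check_consistency(gsto)
        assert rep.passed
        assert rep.sums["E"] == 1
        assert len(rep.sums) == 26

    def test_deficient_premise_reported(self):
        g = make_grammar([
            Production(1, "S", (T("("), NT("B"), T(")")), Fraction(1, 2)),
            Production(2, "S", (T("|"),), Fraction(1, 3)),
            Production(3, "B", (T("|"), T("|"), T("|")), Fraction(1)),
        ])
        rep = check_consistency(g)
        assert not rep.passed
        assert rep.sums["S"] == Fraction(5, 6)

    def test_normal_form_weights_are_not_probabilities(self, star_rational):
        rep = check_consistency(star_rational)
        assert not rep.passed
        assert rep.sums["V"] == Fraction(13243, 10000)


class TestEpsilonLoopFree:
    def test_motif_grammar_is_clean(self, gsto):
        rep = check_epsilon_loop_free(gsto)
        assert rep.epsilon_free and rep.loop_free

    def test_epsilon_rule_detected(self):
        g = load_builtin("Gd")
        rep = check_epsilon_loop_free(g)
        assert not rep.epsilon_free
        assert rep.epsilon_rules == (4,)

    def test_unit_cycle_detected(self):
        g = make_grammar([
            Production(1, "S", (NT("A"),), 1),
            Production(2, "A", (NT("B"),), 1),
            Production(3, "B", (NT("A"),), 1),
            Production(4, "B", (T("|"),), 1),
        ], allow_epsilon=False, weight_mode="integer")
        rep = check_epsilon_loop_free(g)
        assert not rep.loop_free
        assert set(rep.unit_cycle) == {"A", "B"}


class TestDerivationCounting:
    def test_first_nonzero_count(self, gsto):
        d = count_derivations_by_length(gsto, 5)
        assert d == [0, 0, 0, 0, 1]  # "(|||)" is the unique shortest word

    def test_counts_equal_language_sizes(self, gsto, language):
        # empirical unambiguity: one derivation tree per word
        d = count_derivations_by_length(gsto, 12)
        assert d == [len(language[n]) for n in range(1, 13)]

    def test_simple_and_motif_grammars_count_alike(self, gsto):
        # the two grammars generate the same language unambiguously
        gs = load_builtin("Gs")
        assert (count_derivations_by_length(gs, 16)
                == count_derivations_by_length(gsto, 16))


class TestGeneratingFunction:
    def test_identity_holds_for_true_counts(self, gsto):
        counts = count_derivations_by_length(gsto, 20)
        assert all(c == 0 for c in verify_generating_function(counts))

    def test_perturbed_counts_violate_identity(self, gsto):
        counts = count_derivations_by_length(gsto, 20)
        counts[5] += 1  # d_6
        assert any(c != 0 for c in verify_generating_function(counts))

    def test_zero_counts_leave_monomial(self):
        res = verify_generating_function([0] * 10)
        assert res[4] == -1  # the -z^5 term survives
        assert all(c == 0 for i, c in enumerate(res) if i != 4)
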