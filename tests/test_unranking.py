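"""Weighted unranking: bijectivity, orders, sampling, ranking inverse."""

import math
from collections import Counter
from fractions import Fraction

import pytest

from rnaunrank.classes import build_tables, grammar_to_spec
from rnaunrank.grammars import load_builtin
from rnaunrank.reweight import prepare_integer_grammar
from rnaunrank.rnf import to_rnf
from rnaunrank.training import chart_rule_counts
from rnaunrank.unranking import (
    RankError,
    SamplerConfig,
    count_probes,
    rank_structure,
    sample,
    unrank_class,
)

ORDERS = ("sequential", "boustrophedon")


def brute_weight(grammar, word):
    class _W:
        pass
    w = _W()
    w.word = word
    out = 1
    for rid, c in chart_rule_counts(grammar, w).items():
        out *= int(grammar.rule(rid).weight) ** c
    return out


class TestUnrank:
    @pytest.mark.parametrize("order", ORDERS)
    def test_unique_size_five_structure(self, weighted_table, order):
        total = weighted_table.size("S'", 5)
        assert total > 0
        for i in (0, total // 2, total - 1):
            assert unrank_class(weighted_table, "S'", 5, i, order) == "(|||)"

    @pytest.mark.parametrize("order", ORDERS)
    def test_uniform_full_range_is_a_bijection(self, uniform_table, language, order):
        for n in range(5, 11):
            total = uniform_table.size("S'", n)
            words = [unrank_class(uniform_table, "S'", n, i, order)
                     for i in range(total)]
            assert len(set(words)) == total
            assert sorted(words) == sorted(s.word for s in language[n])

    def test_orders_permute_but_agree_as_multisets(self, uniform_table):
        n = 8
        total = uniform_table.size("S'", n)
        seq = [unrank_class(uniform_table, "S'", n, i, "sequential")
               for i in range(total)]
        bous = [unrank_class(uniform_table, "S'", n, i, "boustrophedon")
                for i in range(total)]
        assert Counter(seq) == Counter(bous)
        assert seq != bous  # genuinely different bijections

    @pytest.mark.parametrize("order", ORDERS)
    def test_weighted_full_range_multiplicities_on_toy_grammar(self, order):
        # exact-mode reweighting of the small teaching grammar keeps class
        # sizes small enough to enumerate every rank
        gd = load_builtin("Gd_eps_free")
        rep = prepare_integer_grammar(to_rnf(gd).result, digits=None)
        table = build_tables(grammar_to_spec(rep.result), 7)
        for n in range(1, 8):
            total = table.size("S", n)
            multiset = Counter(unrank_class(table, "S", n, i, order)
                               for i in range(total))
            for word, mult in multiset.items():
                assert mult == brute_weight(rep.result, word)

    def test_rank_out_of_range(self, weighted_table):
        with pytest.raises(RankError):
            unrank_class(weighted_table, "S'", 5, weighted_table.size("S'", 5))


class TestRankStructure:
    def test_minimal_structure_has_rank_zero(self, weighted_table):
        assert rank_structure(weighted_table, "(|||)") == 0

    @pytest.mark.parametrize("order", ORDERS)
    def test_round_trip_is_exhaustive_at_size_seven(self, weighted_table,
                                                    language, order):
        for s in language[7]:
            r = rank_structure(weighted_table, s, order)
            assert unrank_class(weighted_table, "S'", 7, r, order) == s.word

    @pytest.mark.parametrize("order", ORDERS)
    def test_first_copy_property_on_uniform_weights(self, uniform_table, order):
        # with unit weights rank(unrank(i)) == i exactly
        n = 9
        for i in range(uniform_table.size("S'", n)):
            w = unrank_class(uniform_table, "S'", n, i, order)
            assert rank_structure(uniform_table, w, order) == i

    def test_invalid_structure_rejected(self, weighted_table):
        with pytest.raises(ValueError):
            rank_structure(weighted_table, "(||)")


class TestSample:
    def test_single_support_size(self, weighted_table):
        cfg = SamplerConfig(table=weighted_table, seed=99)
        assert [s.word for s in sample(weighted_table, 5, 3, cfg)] == ["(|||)"] * 3

    def test_empty_size_rejected(self, weighted_table):
        with pytest.raises(ValueError, match="no structures"):
            sample(weighted_table, 4, 1, SamplerConfig(table=weighted_table))

    def test_seeded_determinism(self, weighted_table):
        a = sample(weighted_table, 12, 50, SamplerConfig(table=weighted_table, seed=7))
        b = sample(weighted_table, 12, 50, SamplerConfig(table=weighted_table, seed=7))
        c = sample(weighted_table, 12, 50, SamplerConfig(table=weighted_table, seed=8))
        assert [s.word for s in a] == [s.word for s in b]
        assert [s.word for s in a] != [s.word for s in c]

    def test_empirical_distribution_tracks_exact_law(self, star_integer,
                                                     weighted_table, language):
        # moderate-m sanity check; the full goodness-of-fit experiment lives
        # in the acceptance suite
        from scipy import stats as sstats

        n, m = 9, 8000
        exact = {s.word: brute_weight(star_integer, s.word) for s in language[n]}
        total = sum(exact.values())
        drawn = Counter(
            s.word for s in sample(weighted_table, n, m,
                                   SamplerConfig(table=weighted_table, seed=13)))
        words = sorted(exact, key=exact.get, reverse=True)
        observed, expected = [], []
        acc_o = acc_e = 0.0
        for w in words:
            e = m * exact[w] / total
            if e < 5:
                acc_o += drawn.get(w, 0)
                acc_e += e
            else:
                observed.append(drawn.get(w, 0))
                expected.append(e)
        observed.append(acc_o)
        expected.append(acc_e)
        _, p = sstats.chisquare(observed, expected)
        assert p > 1e-3


class TestWorkBound:
    def test_boustrophedon_probe_growth_is_subquadratic(self, default_sampler):
        # doubling experiment on averaged seeded ranks: n log n doubles by
        # ~2.2x at these sizes, a quadratic bound by 4x
        import random

        s = default_sampler
        s.ensure(256)
        root_total = {n: s.table.size("S'", n) for n in (64, 128, 256)}
        rng = random.Random(4242)

        def avg_probes(n, order):
            ranks = [rng.randrange(root_total[n]) for _ in range(12)]
            return sum(count_probes(s.table, n, i, order) for i in ranks) / 12

        bous = {n: avg_probes(n, "boustrophedon") for n in (64, 128, 256)}
        assert bous[128] / bous[64] < 3.2
        assert bous[256] / bous[128] < 3.2

    def test_sequential_worst_case_exceeds_boustrophedon(self, default_sampler):
        s = default_sampler
        s.ensure(256)
        n = 256
        worst = s.table.size("S'", n) - 1
        seq = count_probes(s.table, n, worst, "sequential")
        bous = count_probes(s.table, n, worst, "boustrophedon")
        assert seq > 2 * bous
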