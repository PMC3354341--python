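"""Integer reweighting of a normal-form grammar.

Rational rule weights are turned into integers without changing the
relative weight of any two words of the same size: axiom rules are scaled
by the common denominator s of their weights, and every other rule A -> α
by c^(|α|-1) where c is the common denominator of all non-axiom weights.
Because a rule lengthens the sentential form by |α|-1, every word w then
carries the integer weight s * c^(|w|-1) * weight(w).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm

from .grammars import Production, WeightedGrammar


def round_half_away(x: Fraction, digits: int) -> Fraction:
    """Round to ``digits`` decimals, ties away from zero, exactly."""
    scaled = x * 10**digits
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    return Fraction(q, 10**digits)


def round_weights(g: WeightedGrammar, digits: int = 4) -> WeightedGrammar:
    """Round every rule weight to ``digits`` decimals (exact rationals).

    A weight that would round to zero silently deletes words from the
    language, so the precision is escalated grammar-wide until every
    rounded weight is positive.
    """
    if digits < 1:
        raise ValueError("digits must be >= 1")
    if g.weight_mode != "rational":
        raise ValueError("round_weights expects a rational-weighted grammar")
    d = digits
    while True:
        rounded = {r.id: round_half_away(Fraction(r.weight), d) for r in g.rules}
        if all(w > 0 for w in rounded.values()):
            break
        d += 1
    return g.with_weights(rounded, stochastic=False,
                          name=f"{g.name}:r{d}" if g.name else f"rounded{d}")


def common_denominators(g: WeightedGrammar) -> tuple[int, int]:
    """(s, c): least common denominators of axiom-rule / other-rule weights."""
    s = 1
    c = 1
    for r in g.rules:
        den = Fraction(r.weight).denominator
        if r.premise == g.axiom:
            s = lcm(s, den)
        else:
            c = lcm(c, den)
    return s, c


@dataclass
class ReweightReport:
    s: int
    c: int
    digits: int | None          # rounding precision used, None in exact mode
    result: WeightedGrammar

    def to_json(self) -> dict:
        return {"s": self.s, "c": self.c, "digits": self.digits,
                "result": self.result.to_json()}


def reweight(g: WeightedGrammar) -> ReweightReport:
    """Convert a normal-form grammar's rational weights to integers.

    Requires that every non-axiom rule with a length-1 conclusion already
    has an integral weight (normal-form condition; the chain rules all have
    weight 1), because such rules are scaled by c^0 = 1.
    """
    for r in g.rules:
        if r.weight == 0:
            raise ValueError(f"rule {r.id} has weight 0")
        if (r.premise != g.axiom and len(r.conclusion) == 1
                and Fraction(r.weight).denominator != 1):
            raise ValueError(
                f"rule {r.id} ({r.premise} -> {r.conclusion[0].name}) has a "
                f"non-integral weight {r.weight} on a length-1 conclusion; "
                "the grammar is not in reweighting normal form")
        if r.premise == g.axiom and len(r.conclusion) > 1:
            raise ValueError(
                f"axiom rule {r.id} has conclusion length {len(r.conclusion)}; "
                "the grammar is not in reweighting normal form")
    s, c = common_denominators(g)
    weights: dict[int, int] = {}
    for r in g.rules:
        if r.premise == g.axiom:
            mu = Fraction(r.weight) * s
        else:
            mu = Fraction(r.weight) * c ** (len(r.conclusion) - 1)
        assert mu.denominator == 1, (r, mu)
        weights[r.id] = mu.numerator
    result = g.with_weights(weights, weight_mode="integer",
                            name=(g.name + ":int") if g.name else "reweighted")
    return ReweightReport(s=s, c=c, digits=None, result=result)


def prepare_integer_grammar(g_rnf: WeightedGrammar, digits: int | None = 4
                            ) -> ReweightReport:
    """Round a normal-form grammar and reweight it to integers in one step.

    ``digits=None`` skips rounding (exact mode): the true least common
    denominators are used, which can be astronomically large for trained
    grammars -- sound, but rarely what you want.
    """
    g = g_rnf if digits is None else round_weights(g_rnf, digits)
    report = reweight(g)
    report.digits = digits
    return report
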