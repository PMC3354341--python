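"""Reweighting normal form (RNF) of a weighted grammar.

An epsilon-free, loop-free WCFG is transformed so that every non-axiom rule
either lengthens the sentential form or carries an (eventually) integral
weight.  The transformation collapses all non-lengthening derivation chains
A => A1 => ... => X into fresh weight-1 "chain" nonterminals named
``A_{X,via}`` and substitutes them into the surviving rules, preserving the
weight of every word exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product as iter_product

from .grammars import NT, Production, Symbol, WeightedGrammar, check_epsilon_loop_free


@dataclass(frozen=True)
class Chain:
    """A maximal-or-prefix unit-derivation chain ``source =>+ target``.

    ``weight`` is the exact product of the traversed unit-rule weights;
    ``via`` spells the intermediate nonterminals (empty for a direct step).
    """

    source: str
    target: Symbol
    weight: Fraction
    via: tuple[str, ...]
    rule_ids: tuple[int, ...]

    @property
    def symbol_name(self) -> str:
        via = "".join(self.via) or "ε"
        return f"{self.source}_{{{self.target.name},{via}}}"


@dataclass
class ChainTable:
    """Chains grouped per source nonterminal, in canonical enumeration order."""

    targets: dict[str, tuple[Chain, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.targets.values())

    def all_chains(self) -> list[Chain]:
        return [c for chains in self.targets.values() for c in chains]


def _require_rnf_input(g: WeightedGrammar) -> None:
    rep = check_epsilon_loop_free(g)
    if not rep.epsilon_free:
        raise ValueError(
            f"grammar is not epsilon-free (epsilon rules {rep.epsilon_rules}, "
            f"axiom in conclusions of {rep.axiom_in_conclusion})")
    if not rep.loop_free:
        raise ValueError(f"grammar has a unit-derivation cycle {rep.unit_cycle}")
    zero = [r.id for r in g.rules if r.weight == 0]
    if zero:
        raise ValueError(f"rules with weight 0 cannot be normalized: {zero}")


def collect_chains(g: WeightedGrammar) -> ChainTable:
    """All unit-derivation chains from every non-axiom nonterminal.

    Per source the enumeration is breadth-first by chain length; chains of
    equal length that end in a terminal precede those ending in a
    nonterminal, remaining ties broken by the position of the parent chain
    and the id of the extending rule.  Loop-freeness bounds every chain.
    """
    _require_rnf_input(g)
    table = ChainTable()
    for a in g.nonterminals:
        if a == g.axiom:
            continue
        depth: list[Chain] = []
        for r in g.rules_for(a):
            if len(r.conclusion) == 1:
                depth.append(Chain(a, r.conclusion[0], Fraction(r.weight), (), (r.id,)))
        chains: list[Chain] = []
        while depth:
            chains.extend(depth)
            nxt: list[tuple[int, int, Chain]] = []
            for pos, c in enumerate(depth):
                if c.target.is_terminal:
                    continue
                for r in g.rules_for(c.target.name):
                    if len(r.conclusion) == 1:
                        nxt.append((pos, r.id, Chain(
                            a, r.conclusion[0],
                            c.weight * Fraction(r.weight),
                            c.via + (c.target.name,),
                            c.rule_ids + (r.id,),
                        )))
            nxt.sort(key=lambda t: (0 if t[2].target.is_terminal else 1, t[0], t[1]))
            depth = [c for _, _, c in nxt]
        if chains:
            table.targets[a] = tuple(chains)
    return table


@dataclass
class RnfReport:
    """Every intermediate artifact of the five transformation steps."""

    input_grammar: WeightedGrammar
    removed_unit_rules: tuple[Production, ...]
    chains: ChainTable
    chain_rules: tuple[Production, ...]
    substituted_rules: tuple[Production, ...]   # step-3 output, before step 4
    dead_symbols: frozenset[str]
    dead_rules: tuple[Production, ...]
    axiom_fixes: tuple[tuple[Production, Production], ...]
    result: WeightedGrammar

    def to_json(self) -> dict:
        def rule_json(r: Production) -> dict:
            w = r.weight
            weight = ({"num": w.numerator, "den": w.denominator}
                      if isinstance(w, Fraction) else int(w))
            return {"id": r.id, "premise": r.premise,
                    "conclusion": [s.name for s in r.conclusion], "weight": weight}

        return {
            "removed_unit_rules": [rule_json(r) for r in self.removed_unit_rules],
            "chains": [
                {"source": c.source, "target": c.target.name,
                 "via": list(c.via), "symbol": c.symbol_name,
                 "weight": {"num": c.weight.numerator, "den": c.weight.denominator}}
                for c in self.chains.all_chains()
            ],
            "chain_rules": [rule_json(r) for r in self.chain_rules],
            "substituted_rules": [rule_json(r) for r in self.substituted_rules],
            "dead_symbols": sorted(self.dead_symbols),
            "dead_rules": [rule_json(r) for r in self.dead_rules],
            "axiom_fixes": [[rule_json(a), rule_json(b)] for a, b in self.axiom_fixes],
            "result": self.result.to_json(),
        }


def _substituted_variants(rule: Production,
                          chains: ChainTable) -> list[tuple[tuple[Symbol, ...], Fraction]]:
    """All substitution variants of one rule, in canonical emission order.

    Occurrences of chain sources in the conclusion are enumerated
    mixed-radix, the occurrence with the most chains varying fastest (ties:
    leftmost occurrence faster); digit 0 keeps the occurrence unsubstituted.
    The all-zero variant (the original conclusion) comes first.
    """
    occs = [(pos, chains.targets[s.name])
            for pos, s in enumerate(rule.conclusion)
            if not s.is_terminal and s.name in chains.targets]
    if not occs:
        return [(rule.conclusion, Fraction(rule.weight))]
    # fastest-varying first: more chains first, then leftmost
    occs_sorted = sorted(enumerate(occs), key=lambda t: (-len(t[1][1]), t[1][0]))
    radii = [range(len(ch) + 1) for _, (_, ch) in occs_sorted]
    out = []
    # iter_product varies the LAST factor fastest; feed slowest digits first
    for digits in iter_product(*reversed(radii)):
        digits = tuple(reversed(digits))
        conclusion = list(rule.conclusion)
        weight = Fraction(rule.weight)
        for (ord_pos, (pos, chlist)), d in zip(occs_sorted, digits):
            if d:
                chain = chlist[d - 1]
                conclusion[pos] = NT(chain.symbol_name)
                weight *= chain.weight
        out.append((tuple(conclusion), weight))
    return out


def to_rnf(g: WeightedGrammar) -> RnfReport:
    """Transform ``g`` into reweighting normal form (five steps).

    1. remove unit rules A -> X with A != axiom and gather all chains;
    2. add one weight-1 rule ``A_{X,via} -> X`` per chain;
    3. substitute every combination of chains into the surviving rules,
       multiplying weights;
    4. delete nonterminals that no longer occur as a premise together with
       every rule mentioning them;
    5. split axiom rules whose conclusion is longer than one symbol.

    The result generates the same words with exactly the same weights.
    """
    _require_rnf_input(g)
    chains = collect_chains(g)

    removed = tuple(r for r in g.rules
                    if r.premise != g.axiom and len(r.conclusion) == 1)
    removed_ids = {r.id for r in removed}
    surviving = [r for r in g.rules if r.id not in removed_ids]

    chain_symbols = [c.symbol_name for c in chains.all_chains()]
    chain_rule_list = [
        Production(0, c.symbol_name, (c.target,), Fraction(1))
        for c in chains.all_chains()
    ]

    # step 3
    substituted: list[Production] = []
    for r in surviving:
        for conclusion, weight in _substituted_variants(r, chains):
            substituted.append(Production(len(substituted) + 1, r.premise,
                                          conclusion, weight))

    # step 4: iterate until stable (removing rules can orphan more symbols)
    main = list(substituted)
    dead_symbols: set[str] = set()
    dead_rules: list[Production] = []
    while True:
        premises = {r.premise for r in main} | {r.premise for r in chain_rule_list}
        used_nts = set(g.nonterminals) | set(chain_symbols)
        newly_dead = (used_nts - premises) - dead_symbols
        if not newly_dead:
            break
        dead_symbols |= newly_dead
        still = []
        for r in main:
            if any((not s.is_terminal) and s.name in dead_symbols
                   for s in r.conclusion):
                dead_rules.append(r)
            else:
                still.append(r)
        main = still

    # step 5: axiom conclusions must have length <= 1
    axiom_fixes: list[tuple[Production, Production]] = []
    fixed_main: list[Production] = []
    aux_rules: list[Production] = []
    for r in main:
        if r.premise == g.axiom and len(r.conclusion) > 1:
            aux = f"{g.axiom}_{{{len(axiom_fixes) + 1}}}"
            top = Production(0, g.axiom, (NT(aux),), Fraction(r.weight))
            body = Production(0, aux, r.conclusion, Fraction(1))
            axiom_fixes.append((top, body))
            fixed_main.append(top)
            aux_rules.append(body)
        else:
            fixed_main.append(r)
    fixed_main.extend(aux_rules)

    # assemble: main rules first, then the chain rules, ids re-numbered
    final_rules = [
        Production(i, r.premise, r.conclusion, r.weight)
        for i, r in enumerate(fixed_main + chain_rule_list, start=1)
    ]
    nts = ([a for a in g.nonterminals if a not in dead_symbols]
           + [f"{g.axiom}_{{{k + 1}}}" for k in range(len(axiom_fixes))]
           + chain_symbols)
    result = WeightedGrammar(
        nts, g.axiom, final_rules, weight_mode="rational",
        name=(g.name + ":rnf") if g.name else "rnf",
    )
    return RnfReport(
        input_grammar=g,
        removed_unit_rules=removed,
        chains=chains,
        chain_rules=tuple(chain_rule_list),
        substituted_rules=tuple(substituted),
        dead_symbols=frozenset(dead_symbols),
        dead_rules=tuple(dead_rules),
        axiom_fixes=tuple(axiom_fixes),
        result=result,
    )
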