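"""Weighted and stochastic context-free grammars over the bar-bracket alphabet.

A secondary structure is written over the three terminals ``(``, ``)`` and
``|`` (a bar per unpaired base, a bracket pair per base pair).  Grammars are
immutable; every transformation in the pipeline returns a new grammar.  Rule
weights are exact :class:`fractions.Fraction` values or arbitrary-precision
integers -- no floating point is ever stored on a rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

TERMINALS = ("(", ")", "|")


@dataclass(frozen=True)
class Symbol:
    """A terminal or nonterminal grammar symbol."""

    kind: str  # "terminal" | "nonterminal"
    name: str

    def __post_init__(self) -> None:
        if self.kind not in ("terminal", "nonterminal"):
            raise ValueError(f"unknown symbol kind {self.kind!r}")
        if self.kind == "terminal" and self.name not in TERMINALS:
            raise ValueError(f"terminal must be one of {TERMINALS}, got {self.name!r}")

    @property
    def is_terminal(self) -> bool:
        return self.kind == "terminal"

    def __str__(self) -> str:
        return self.name


def T(ch: str) -> Symbol:
    return Symbol("terminal", ch)


def NT(name: str) -> Symbol:
    return Symbol("nonterminal", name)


@dataclass(frozen=True)
class Production:
    """A weighted production rule ``premise -> conclusion``.

    ``id`` is the ordinal position in the grammar's listing; it is stable and
    defines every tie-breaking order downstream (unranking, substitution
    enumeration, serialization).
    """

    id: int
    premise: str
    conclusion: tuple[Symbol, ...]
    weight: Fraction | int

    def __post_init__(self) -> None:
        # weight 0 is tolerated only so that relative-frequency training can
        # report unobserved rules; the normal-form/reweighting pipeline
        # refuses such rules at entry.
        if self.weight < 0:
            raise ValueError(f"rule {self.id}: weight must be >= 0, got {self.weight}")

    @property
    def lengthening(self) -> int:
        """How much the rule lengthens a sentential form (|conclusion| - 1)."""
        return len(self.conclusion) - 1

    def __str__(self) -> str:
        rhs = " ".join(s.name for s in self.conclusion) or "eps"
        return f"[{self.id}] {self.weight}: {self.premise} -> {rhs}"


class WeightedGrammar:
    """An immutable WCFG/SCFG with exact rational or integer rule weights."""

    def __init__(
        self,
        nonterminals: Sequence[str],
        axiom: str,
        rules: Iterable[Production],
        *,
        weight_mode: str = "rational",
        stochastic: bool = False,
        allow_epsilon: bool = False,
        name: str = "",
    ) -> None:
        self.nonterminals: tuple[str, ...] = tuple(nonterminals)
        self.terminals: frozenset[str] = frozenset(TERMINALS)
        self.axiom = axiom
        self.rules: tuple[Production, ...] = tuple(rules)
        self.weight_mode = weight_mode
        self.stochastic = stochastic
        self.allow_epsilon = allow_epsilon
        self.name = name
        self._validate()
        self._by_premise: dict[str, tuple[Production, ...]] = {}
        for r in self.rules:
            self._by_premise.setdefault(r.premise, ())
        for r in self.rules:
            self._by_premise[r.premise] = self._by_premise[r.premise] + (r,)

    def _validate(self) -> None:
        if len(set(self.nonterminals)) != len(self.nonterminals):
            raise ValueError("duplicate nonterminal names")
        nts = set(self.nonterminals)
        if self.axiom not in nts:
            raise ValueError(f"axiom {self.axiom!r} not among nonterminals")
        if self.weight_mode not in ("rational", "integer"):
            raise ValueError(f"bad weight_mode {self.weight_mode!r}")
        premises = set()
        for r in self.rules:
            if r.premise not in nts:
                raise ValueError(f"rule {r.id}: premise {r.premise!r} undeclared")
            if not r.conclusion and not self.allow_epsilon:
                raise ValueError(f"rule {r.id}: empty conclusion in non-epsilon grammar")
            for s in r.conclusion:
                if not s.is_terminal and s.name not in nts:
                    raise ValueError(f"rule {r.id}: symbol {s.name!r} undeclared")
            premises.add(r.premise)
        missing = nts - premises
        if missing:
            raise ValueError(f"nonterminals with no rule: {sorted(missing)}")
        if self.stochastic:
            rep = check_consistency(self)
            if not rep.passed:
                bad = {p: str(s) for p, s in rep.sums.items() if s != 1}
                raise ValueError(f"stochastic grammar with premise sums != 1: {bad}")

    def rules_for(self, premise: str) -> tuple[Production, ...]:
        return self._by_premise.get(premise, ())

    def rule(self, rule_id: int) -> Production:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def weight_of(self, premise: str, conclusion: str) -> Fraction | int:
        """Weight of the unique rule ``premise -> conclusion``.

        ``conclusion`` is given as a whitespace-separated symbol string, e.g.
        ``"( L )"`` or simply ``"S"``.
        """
        want = tuple(conclusion.split())
        for r in self.rules_for(premise):
            if tuple(s.name for s in r.conclusion) == want:
                return r.weight
        raise KeyError(f"no rule {premise} -> {conclusion}")

    def with_weights(self, weights: Mapping[int, Fraction | int], *,
                     weight_mode: str | None = None,
                     stochastic: bool | None = None,
                     name: str | None = None) -> "WeightedGrammar":
        """A copy of this grammar with some rule weights replaced (by rule id)."""
        new_rules = tuple(
            Production(r.id, r.premise, r.conclusion, weights.get(r.id, r.weight))
            for r in self.rules
        )
        return WeightedGrammar(
            self.nonterminals, self.axiom, new_rules,
            weight_mode=self.weight_mode if weight_mode is None else weight_mode,
            stochastic=self.stochastic if stochastic is None else stochastic,
            allow_epsilon=self.allow_epsilon,
            name=self.name if name is None else name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGrammar):
            return NotImplemented
        return (
            self.nonterminals == other.nonterminals
            and self.axiom == other.axiom
            and self.rules == other.rules
            and self.weight_mode == other.weight_mode
            and self.stochastic == other.stochastic
        )

    def __repr__(self) -> str:
        return (f"WeightedGrammar({self.name or 'anonymous'}: "
                f"{len(self.nonterminals)} nonterminals, {len(self.rules)} rules, "
                f"axiom {self.axiom})")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> dict:
        def enc_weight(w: Fraction | int) -> dict | int:
            if isinstance(w, Fraction):
                return {"num": w.numerator, "den": w.denominator}
            return int(w)

        return {
            "name": self.name,
            "axiom": self.axiom,
            "terminals": sorted(self.terminals),
            "nonterminals": list(self.nonterminals),
            "weight_mode": self.weight_mode,
            "stochastic": self.stochastic,
            "allow_epsilon": self.allow_epsilon,
            "rules": [
                {
                    "id": r.id,
                    "premise": r.premise,
                    "conclusion": [s.name for s in r.conclusion],
                    "weight": enc_weight(r.weight),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "WeightedGrammar":
        nts = set(data["nonterminals"])

        def dec_weight(w) -> Fraction | int:
            if isinstance(w, dict):
                return Fraction(w["num"], w["den"])
            return int(w)

        rules = [
            Production(
                r["id"],
                r["premise"],
                tuple(T(s) if s in TERMINALS and s not in nts else NT(s)
                      for s in r["conclusion"]),
                dec_weight(r["weight"]),
            )
            for r in data["rules"]
        ]
        return cls(
            data["nonterminals"], data["axiom"], rules,
            weight_mode=data.get("weight_mode", "rational"),
            stochastic=data.get("stochastic", False),
            allow_epsilon=data.get("allow_epsilon", False),
            name=data.get("name", ""),
        )

    def fingerprint(self) -> str:
        """Stable hash of rules and weights, used to tag size tables."""
        payload = json.dumps(self.to_json(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# structural checks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsistencyReport:
    sums: Mapping[str, Fraction]
    passed: bool


def check_consistency(g: WeightedGrammar) -> ConsistencyReport:
    """Per-premise exact rational weight sums; passes iff every sum is 1."""
    sums: dict[str, Fraction] = {}
    for r in g.rules:
        sums[r.premise] = sums.get(r.premise, Fraction(0)) + Fraction(r.weight)
    return ConsistencyReport(sums, all(s == 1 for s in sums.values()))


@dataclass(frozen=True)
class EpsilonLoopReport:
    epsilon_free: bool
    loop_free: bool
    epsilon_rules: tuple[int, ...]
    axiom_in_conclusion: tuple[int, ...]
    unit_cycle: tuple[str, ...]


def check_epsilon_loop_free(g: WeightedGrammar) -> EpsilonLoopReport:
    """Check the structural preconditions of the normal-form transformation.

    epsilon-free: no rule has an empty conclusion and the axiom never occurs
    in a conclusion.  loop-free: the unit-derivation graph (edges A -> B for
    rules whose conclusion is the single nonterminal B) is acyclic; together
    with epsilon-freeness this rules out any derivation A =>+ A.
    """
    eps_rules = tuple(r.id for r in g.rules if not r.conclusion)
    axiom_hits = tuple(
        r.id for r in g.rules
        if any((not s.is_terminal) and s.name == g.axiom for s in r.conclusion)
    )
    # unit graph cycle detection (iterative DFS, colors: 0 new / 1 open / 2 done)
    unit: dict[str, list[str]] = {a: [] for a in g.nonterminals}
    for r in g.rules:
        if len(r.conclusion) == 1 and not r.conclusion[0].is_terminal:
            unit[r.premise].append(r.conclusion[0].name)
    color = {a: 0 for a in g.nonterminals}
    cycle: tuple[str, ...] = ()
    for start in g.nonterminals:
        if color[start] or cycle:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        path = [start]
        color[start] = 1
        while stack and not cycle:
            node, i = stack[-1]
            if i < len(unit[node]):
                stack[-1] = (node, i + 1)
                nxt = unit[node][i]
                if color[nxt] == 1:
                    cycle = tuple(path[path.index(nxt):]) + (nxt,)
                elif color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, 0))
                    path.append(nxt)
            else:
                color[node] = 2
                stack.pop()
                path.pop()
    return EpsilonLoopReport(
        epsilon_free=not eps_rules and not axiom_hits,
        loop_free=not cycle,
        epsilon_rules=eps_rules,
        axiom_in_conclusion=axiom_hits,
        unit_cycle=cycle,
    )


# ---------------------------------------------------------------------------
# derivation counting and the structure generating function
# ---------------------------------------------------------------------------


def count_derivations_by_length(g: WeightedGrammar, N: int) -> list[int]:
    """Number of derivation trees d_n over all words of length n, 1 <= n <= N.

    All weights are treated as 1.  For an unambiguous grammar d_n equals the
    number of words of length n in the language; comparing the sequence with
    an exhaustive enumeration of the language is the package's empirical
    unambiguity check.

    Epsilon rules are supported as long as no derivation A =>+ A exists
    through nullable symbols (detected and refused); unit-loop-free is
    always required.
    """
    rep = check_epsilon_loop_free(g)
    if not rep.loop_free:
        raise ValueError(f"grammar has a unit-derivation cycle {rep.unit_cycle}")

    # minimal derivable length per nonterminal (fixpoint; inf = unproductive)
    min_len: dict[str, float] = {a: float("inf") for a in g.nonterminals}
    changed = True
    while changed:
        changed = False
        for r in g.rules:
            v = sum(1 if s.is_terminal else min_len[s.name] for s in r.conclusion)
            if v < min_len[r.premise]:
                min_len[r.premise] = v
                changed = True
    bad = [a for a, v in min_len.items() if v == float("inf")]
    if bad:
        raise ValueError(f"unproductive nonterminals: {bad}")

    nt_memo: dict[tuple[str, int], int] = {}
    seq_memo: dict[tuple[int, int, int], int] = {}
    active: set[tuple[str, int]] = set()

    def count_nt(a: str, n: int) -> int:
        key = (a, n)
        if key in nt_memo:
            return nt_memo[key]
        if key in active:
            raise ValueError(
                f"derivation {a} =>+ {a} of length 0 detected (nullable loop); "
                "counting would diverge")
        active.add(key)
        total = 0
        for r in g.rules_for(a):
            total += count_seq(r, 0, n)
        active.discard(key)
        nt_memo[key] = total
        return total

    def count_seq(r: Production, pos: int, n: int) -> int:
        m = len(r.conclusion)
        if pos == m:
            return 1 if n == 0 else 0
        rest_min = sum(1 if s.is_terminal else int(min_len[s.name])
                       for s in r.conclusion[pos:])
        if n < rest_min:
            return 0
        key = (r.id, pos, n)
        if key in seq_memo:
            return seq_memo[key]
        sym = r.conclusion[pos]
        if sym.is_terminal:
            out = count_seq(r, pos + 1, n - 1)
        elif pos == m - 1:
            out = count_nt(sym.name, n)
        else:
            lo = int(min_len[sym.name])
            hi = n - (rest_min - lo)
            out = 0
            for k in range(lo, hi + 1):
                left = count_nt(sym.name, k)
                if left:
                    out += left * count_seq(r, pos + 1, n - k)
        seq_memo[key] = out
        return out

    return [count_nt(g.axiom, n) for n in range(1, N + 1)]


def _poly_mul(a: list[int], b: list[int], N: int) -> list[int]:
    out = [0] * (N + 1)
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        top = min(len(b), N + 1 - i)
        for j in range(top):
            if b[j]:
                out[i + j] += ai * b[j]
    return out


def verify_generating_function(counts: Sequence[int], N: int | None = None) -> list[int]:
    """Residual coefficients of the structure-generating-function identity.

    The counting sequence of the language (minimum hairpin length 3, at least
    one pair) satisfies, with S(z) = sum_n d_n z^n,

        -z^5 + S(z) (z - 1) (-1 + z (2 - S(z) (z - 1) z + z^4)) = 0.

    Substitutes the truncated series and returns the coefficients of
    z^1 .. z^N of the left-hand side; on a correct sequence all are zero.
    """
    if N is None:
        N = len(counts)
    S = [0] * (N + 1)
    for n, d in enumerate(counts[:N], start=1):
        S[n] = d
    zm1 = [0] * (N + 1)
    zm1[0] = -1
    if N >= 1:
        zm1[1] = 1
    s_zm1 = _poly_mul(S, zm1, N)  # S(z)(z-1)
    inner = [0] * (N + 1)  # 2 - S(z)(z-1) z + z^4
    inner[0] = 2
    for i in range(N):
        inner[i + 1] -= s_zm1[i]
    if N >= 4:
        inner[4] += 1
    bracket = [0] * (N + 1)  # -1 + z * inner
    bracket[0] = -1
    for i in range(N):
        bracket[i + 1] += inner[i]
    lhs = _poly_mul(s_zm1, bracket, N)
    if N >= 5:
        lhs[5] -= 1
    return lhs[1:N + 1]


# ---------------------------------------------------------------------------
# bundled grammars
# ---------------------------------------------------------------------------


def load_builtin(name: str) -> WeightedGrammar:
    """Load one of the bundled grammars.

    ========================  ====================================================
    name                      grammar
    ========================  ====================================================
    ``Gs``                    simple unambiguous SCFG for the structure language
                              (7 rules over S, A, B, C; unit weights)
    ``Gd``                    small teaching grammar with an epsilon rule
    ``Gd_eps_free``           its epsilon-free form, with illustrative
                              probabilities (1/2 per binary choice)
    ``Gsto_hat``              the 54-rule structure-motif SCFG with the exact
                              trained rational probabilities
    ``Gsto_hat_star_rational``  its reweighting normal form with the published
                              4-decimal weights (not a probability distribution)
    ``Gsto_hat_star_integer``  the same grammar with integer weights
                              (10^4-scaled) plus the 32 weight-1 chain rules
    ========================  ====================================================
    """
    from . import _tables

    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin grammar {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    return factory(_tables)


def _mk_gs(_t) -> WeightedGrammar:
    rules = [
        Production(1, "S", (NT("C"), NT("A")), 1),
        Production(2, "A", (T("("), NT("B"), T(")"), NT("C")), 1),
        Production(3, "A", (T("("), NT("B"), T(")"), NT("C"), NT("A")), 1),
        Production(4, "B", (T("|"), T("|"), T("|"), NT("C")), 1),
        Production(5, "B", (NT("C"), NT("A")), 1),
        Production(6, "C", (), 1),
        Production(7, "C", (T("|"), NT("C")), 1),
    ]
    return WeightedGrammar(["S", "A", "B", "C"], "S", rules,
                           weight_mode="integer", allow_epsilon=True, name="Gs")


def _mk_gd(_t) -> WeightedGrammar:
    rules = [
        Production(1, "S", (NT("B"),), Fraction(1)),
        Production(2, "B", (T("("), NT("B"), T(")")), Fraction(1, 2)),
        Production(3, "B", (T("|"), NT("C")), Fraction(1, 2)),
        Production(4, "C", (), Fraction(1, 2)),
        Production(5, "C", (T("|"), NT("C")), Fraction(1, 2)),
    ]
    return WeightedGrammar(["S", "B", "C"], "S", rules,
                           allow_epsilon=True, name="Gd")


def _mk_gd_eps_free(_t) -> WeightedGrammar:
    rules = [
        Production(1, "S", (NT("B"),), Fraction(1)),
        Production(2, "B", (T("("), NT("B"), T(")")), Fraction(1, 2)),
        Production(3, "B", (NT("C"),), Fraction(1, 2)),
        Production(4, "C", (T("|"),), Fraction(1, 2)),
        Production(5, "C", (T("|"), NT("C")), Fraction(1, 2)),
    ]
    return WeightedGrammar(["S", "B", "C"], "S", rules,
                           stochastic=True, name="Gd_eps_free")


def _mk_gsto_hat(t) -> WeightedGrammar:
    rules = [
        Production(i, prem, tuple(T(s) if s in TERMINALS else NT(s) for s in concl.split()),
                   Fraction(num, den))
        for i, (prem, concl, num, den) in enumerate(t.GSTO_HAT_RULES, start=1)
    ]
    return WeightedGrammar(t.GSTO_HAT_NONTERMINALS, "S'", rules,
                           stochastic=True, name="Gsto_hat")


def _star_symbols(t):
    nts = list(t.GSTO_STAR_NONTERMINALS)
    nt_set = set(nts)

    def sym(s: str) -> Symbol:
        return T(s) if s in TERMINALS and s not in nt_set else NT(s)

    return nts, sym


def _mk_gsto_star_rational(t) -> WeightedGrammar:
    nts, sym = _star_symbols(t)
    rules = []
    for i, (prem, concl) in enumerate(t.GSTO_STAR_RULES, start=1):
        if i <= 73:
            w = Fraction(t.TABLE5_WEIGHTS_E4[i - 1], 10**4)
        else:
            w = Fraction(1)
        rules.append(Production(i, prem, tuple(sym(s) for s in concl.split()), w))
    return WeightedGrammar(nts, "S'", rules, name="Gsto_hat_star_rational")


def _mk_gsto_star_integer(t) -> WeightedGrammar:
    nts, sym = _star_symbols(t)
    rules = []
    for i, (prem, concl) in enumerate(t.GSTO_STAR_RULES, start=1):
        w = t.TABLE6_WEIGHTS[i - 1] if i <= 73 else 1
        rules.append(Production(i, prem, tuple(sym(s) for s in concl.split()), w))
    return WeightedGrammar(nts, "S'", rules, weight_mode="integer",
                           name="Gsto_hat_star_integer")


_BUILTINS = {
    "Gs": _mk_gs,
    "Gd": _mk_gd,
    "Gd_eps_free": _mk_gd_eps_free,
    "Gsto_hat": _mk_gsto_hat,
    "Gsto_hat_star_rational": _mk_gsto_star_rational,
    "Gsto_hat_star_integer": _mk_gsto_star_integer,
}
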