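"""Maximum-likelihood training of the structure-motif SCFG.

Because the grammar is unambiguous, each database structure has exactly one
leftmost derivation; rule probabilities are its rule-usage relative
frequencies, kept as exact rationals.  Derivations are recovered by a
linear-time motif-directed decomposer keyed to the bundled grammar's
nonterminal semantics; a generic chart parser over arbitrary grammars
exists as a (size-capped) cross-validation oracle.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .grammars import Production, WeightedGrammar, load_builtin
from .structures import SecondaryStructure

logger = logging.getLogger(__name__)

CHART_PARSER_SIZE_CAP = 60


@dataclass
class RuleCountTable:
    """Per-rule usage counts with per-premise totals."""

    grammar: WeightedGrammar
    counts: Counter = field(default_factory=Counter)

    def add(self, other: "RuleCountTable | Counter", multiplicity: int = 1) -> None:
        src = other.counts if isinstance(other, RuleCountTable) else other
        for rid, c in src.items():
            self.counts[rid] += c * multiplicity

    def premise_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {a: 0 for a in self.grammar.nonterminals}
        for r in self.grammar.rules:
            totals[r.premise] += self.counts.get(r.id, 0)
        return totals

    def __getitem__(self, rule_id: int) -> int:
        return self.counts.get(rule_id, 0)


# ---------------------------------------------------------------------------
# generic chart parser (test oracle)
# ---------------------------------------------------------------------------


def chart_rule_counts(g: WeightedGrammar, s: SecondaryStructure,
                      size_cap: int = CHART_PARSER_SIZE_CAP) -> Counter:
    """Rule multiset of the unique derivation, by exhaustive chart parsing.

    Works for any epsilon-free grammar; cubic-and-worse in the word length,
    hence capped.  Serves as the independent oracle for the motif-directed
    decomposer.
    """
    word = s.word
    n = len(word)
    if n > size_cap:
        raise ValueError(f"structure of size {n} exceeds chart-parser cap {size_cap}")

    nt_memo: dict[tuple[str, int, int], Counter | None] = {}
    seq_memo: dict[tuple[int, int, int, int], Counter | None] = {}

    def parse_nt(a: str, i: int, j: int) -> Counter | None:
        key = (a, i, j)
        if key in nt_memo:
            return nt_memo[key]
        nt_memo[key] = None  # provisional (acyclic unit recursion on loop-free input)
        result = None
        for r in g.rules_for(a):
            sub = parse_seq(r, 0, i, j)
            if sub is not None:
                result = Counter({r.id: 1})
                result.update(sub)
                break
        nt_memo[key] = result
        return result

    def parse_seq(r: Production, pos: int, i: int, j: int) -> Counter | None:
        m = len(r.conclusion)
        if pos == m:
            return Counter() if i == j else None
        key = (r.id, pos, i, j)
        if key in seq_memo:
            return seq_memo[key]
        sym = r.conclusion[pos]
        result = None
        if sym.is_terminal:
            if i < j and word[i] == sym.name:
                result = parse_seq(r, pos + 1, i + 1, j)
        elif pos == m - 1:
            result = parse_nt(sym.name, i, j)
        else:
            for k in range(i + 1, j):
                left = parse_nt(sym.name, i, k)
                if left is None:
                    continue
                rest = parse_seq(r, pos + 1, k, j)
                if rest is not None:
                    result = left + rest
                    break
        seq_memo[key] = result
        return result

    out = parse_nt(g.axiom, 0, n)
    if out is None:
        raise ValueError(f"structure {word!r} is not derivable in grammar {g.name!r}")
    return out


# ---------------------------------------------------------------------------
# motif-directed decomposer for the bundled 54-rule grammar
# ---------------------------------------------------------------------------

_GSTO_SHAPES: tuple[tuple[str, tuple[str, ...]], ...] | None = None


def _gsto_shapes() -> tuple[tuple[str, tuple[str, ...]], ...]:
    global _GSTO_SHAPES
    if _GSTO_SHAPES is None:
        from . import _tables
        _GSTO_SHAPES = tuple(
            (prem, tuple(concl.split())) for prem, concl, _, _ in _tables.GSTO_HAT_RULES
        )
    return _GSTO_SHAPES


def has_specialized_decomposer(g: WeightedGrammar) -> bool:
    """True iff ``g`` has exactly the bundled motif grammar's rule shapes."""
    shapes = tuple((r.premise, tuple(s.name for s in r.conclusion)) for r in g.rules)
    return shapes == _gsto_shapes()


def _segments(word: str, partner: Sequence[int], lo: int, hi: int
              ) -> tuple[list[int], list[tuple[int, int]]]:
    """Bar runs and child pairs of the region [lo, hi): k+1 runs, k children."""
    runs: list[int] = []
    kids: list[tuple[int, int]] = []
    bars = 0
    k = lo
    while k < hi:
        if partner[k] >= 0:
            runs.append(bars)
            bars = 0
            kids.append((k, partner[k]))
            k = partner[k] + 1
        else:
            bars += 1
            k += 1
    runs.append(bars)
    return runs, kids


def _decompose_motif_directed(s: SecondaryStructure) -> Counter:
    """Rule multiset of the unique derivation, in time linear in the size."""
    word = s.word
    partner = s.partner_table()
    out: Counter = Counter()

    def emit(rid: int, times: int = 1) -> None:
        out[rid] += times

    def run_C(b: int) -> None:      # C => |^b
        emit(8)
        emit(9, b - 1)

    def run_U(b: int) -> None:      # U => |^b
        emit(53)
        emit(54, b - 1)

    def run_J(b: int) -> None:      # J => |^b
        emit(41)
        emit(42, b - 1)

    def run_K(b: int) -> None:      # K => |^b
        emit(43)
        emit(44, b - 1)

    def run_D(b: int) -> None:      # D => |^b, b >= 2 (D -> B|)
        emit(22)
        emit(23)
        emit(24, b - 2)

    def hairpin_F(b: int) -> None:  # F => |^b, b >= 3
        if b == 3:
            emit(25)
        elif b == 4:
            emit(26)
        else:
            emit(27)
            emit(28)
            emit(29, b - 5)

    def exterior_E(runs: list[int], kids: list[tuple[int, int]]) -> None:
        # E covers runs[0] (kid 1) runs[1] ... (kid k) runs[k]
        k = len(kids)
        if runs[k]:
            emit(3)          # E -> S C
            run_C(runs[k])
        else:
            emit(2)          # E -> S
        # S covers runs[0] (kid 1) ... (kid k)
        j = k
        while True:
            if j == 1 and runs[0] == 0:
                emit(4)      # S -> A
                helix_A(*kids[0])
                return
            emit(5)          # S -> T A
            helix_A(*kids[j - 1])
            if j == 1:
                emit(7)      # T -> C
                run_C(runs[0])
                return
            emit(6)          # T -> E
            if runs[j - 1]:
                emit(3)
                run_C(runs[j - 1])
            else:
                emit(2)
            j -= 1

    def helix_A(i: int, j: int) -> None:
        emit(10)             # A -> ( L )
        runs, kids = _segments(word, partner, i + 1, j)
        if not kids:
            emit(16)         # L -> F : hairpin
            hairpin_F(runs[0])
            return
        if len(kids) == 1:
            left, right = runs[0], runs[1]
            kid = kids[0]
            if left == 0 and right == 0:
                emit(11)     # L -> A : stacked pair
            elif right == 0:        # bulge left
                emit(17)
                if left == 1:
                    emit(20)        # G -> | A
                else:
                    emit(21)        # G -> D A
                    run_D(left)
            elif left == 0:         # bulge right
                emit(17)
                if right == 1:
                    emit(18)        # G -> A |
                else:
                    emit(19)        # G -> A D
                    run_D(right)
            elif left <= 2 and right <= 2:
                emit(13)            # L -> P : small interior loop
                emit({(1, 1): 30, (1, 2): 31, (2, 1): 32, (2, 2): 33}[(left, right)])
            elif left == 1:         # 1 x (>=3)
                emit(15)            # L -> R
                emit(36)            # R -> | O | |
                emit(40)            # O -> A K
                run_K(right - 2)
            elif left == 2:         # 2 x (>=3)
                emit(14)            # L -> Q
                emit(34)            # Q -> | | O | |
                emit(40)
                run_K(right - 2)
            elif right == 1:        # (>=3) x 1
                emit(15)
                emit(37)            # R -> | | W |
                emit(39)            # W -> J A
                run_J(left - 2)
            else:                   # (>=3) x (>=2)
                emit(14)
                emit(35)            # Q -> | | V |
                emit(38)            # V -> J O
                run_J(left - 2)
                emit(40)
                run_K(right - 1)
            helix_A(*kid)
            return
        # multiloop
        emit(12)             # L -> M
        emit(45)             # M -> X Y
        k = len(kids)

        def branch_X(t: int) -> None:  # branch t with its preceding bar run
            if runs[t - 1]:
                emit(47)     # X -> U A
                run_U(runs[t - 1])
            else:
                emit(46)     # X -> A
            helix_A(*kids[t - 1])

        branch_X(1)
        emit(48)             # Y -> Z
        for t in range(2, k + 1):
            if t < k:
                emit(50)     # Z -> X N
                branch_X(t)
                emit(51)     # N -> Z
            elif runs[k]:
                emit(50)
                branch_X(t)
                emit(52)     # N -> U
                run_U(runs[k])
            else:
                emit(49)     # Z -> X
                branch_X(t)
        return

    emit(1)                  # S' -> E
    runs, kids = _segments(word, partner, 0, len(word))
    exterior_E(runs, kids)
    return out


def derive_rule_counts(g: WeightedGrammar, s: SecondaryStructure) -> RuleCountTable:
    """Rule multiset of the unique derivation of ``s`` under ``g``.

    Uses the linear-time motif-directed decomposer when ``g`` has the bundled
    motif grammar's rule shapes, and the generic chart parser otherwise.
    """
    if has_specialized_decomposer(g):
        counts = _decompose_motif_directed(s)
    else:
        counts = chart_rule_counts(g, s)
    table = RuleCountTable(g)
    table.add(+counts)  # unary + drops zero entries
    return table


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def count_database(g: WeightedGrammar,
                   db: Iterable[SecondaryStructure]) -> RuleCountTable:
    """Accumulated rule counts over a database (duplicates count)."""
    table = RuleCountTable(g)
    if has_specialized_decomposer(g):
        for s in db:
            table.add(_decompose_motif_directed(s))
    else:
        for s in db:
            table.add(chart_rule_counts(g, s))
    return table


def train(g: WeightedGrammar, db: Sequence[SecondaryStructure],
          pseudocount: Fraction | int = 0) -> WeightedGrammar:
    """Estimate rule probabilities as exact relative frequencies.

    weight(rule) = (count + pseudocount) / (premise_total + pseudocount * k)
    with k the number of rules of the premise.  A premise never observed
    receives the uniform distribution (and a logged warning) so the result
    is always a valid SCFG.
    """
    if not db:
        raise ValueError("training database is empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    table = count_database(g, db)
    totals = table.premise_totals()
    weights: dict[int, Fraction] = {}
    for a in g.nonterminals:
        rules = g.rules_for(a)
        total = totals[a]
        if total == 0 and pseudocount == 0:
            logger.warning(
                "premise %s never observed in %d structures; using the uniform "
                "distribution over its %d rules", a, len(db), len(rules))
            for r in rules:
                weights[r.id] = Fraction(1, len(rules))
        else:
            denom = total + Fraction(pseudocount) * len(rules)
            for r in rules:
                weights[r.id] = (table[r.id] + Fraction(pseudocount)) / denom
    return g.with_weights(weights, weight_mode="rational", stochastic=True,
                          name=(g.name + ":trained") if g.name else "trained")


def subsample_stability(g: WeightedGrammar, db: Sequence[SecondaryStructure],
                        fraction: float | Fraction, reps: int, seed: int
                        ) -> dict[int, float]:
    """Variance of re-trained rule probabilities over random subsamples.

    Draws ``reps`` subsets of floor(fraction * len(db)) structures without
    replacement, retrains on each, and returns the per-rule population
    variance of the probability estimates.  Rules whose premise has a single
    production always have variance exactly 0.
    """
    if reps < 2:
        raise ValueError("stability analysis needs reps >= 2")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = int(len(db) * Fraction(fraction))
    if m == 0:
        raise ValueError("fraction yields an empty subsample")
    rng = random.Random(seed)
    samples: dict[int, list[float]] = {r.id: [] for r in g.rules}
    for _ in range(reps):
        sub = rng.sample(list(db), m)
        trained = train(g, sub)
        for r in trained.rules:
            samples[r.id].append(float(r.weight))
    out: dict[int, float] = {}
    for rid, vals in samples.items():
        mean = sum(vals) / reps
        out[rid] = sum((v - mean) ** 2 for v in vals) / reps
    return out
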