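"""Weighted combinatorial classes and exact class-size tables.

An integer-weighted normal-form grammar is read as an admissible
specification: each terminal is an atomic class, each rule conclusion a
(right-associated, binary) cartesian product, each nonterminal a weighted
disjoint union of its conclusion classes.  Weighting a class by an integer
μ formally replicates it μ times, which is how the non-uniform rule
weights enter plain integer counting.

Class sizes obey

    size(ε, n)      = [n = 0]
    size(Z_t, n)    = [n = 1]
    size(Σ μ_k C_k, n) = Σ μ_k · size(C_k, n)
    size(A × B, n)  = Σ_j size(A, j) · size(B, n - j)

and are computed bottom-up with arbitrary-precision integers; the full
table up to size N costs O(N^2) coefficient operations.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from typing import IO, Iterable, Union as TUnion

from .grammars import WeightedGrammar


# -- class expressions ------------------------------------------------------


@dataclass(frozen=True)
class Neutral:
    def key(self) -> str:
        return "ε"


@dataclass(frozen=True)
class Atomic:
    char: str

    def key(self) -> str:
        return f"Z{self.char}"


@dataclass(frozen=True)
class Ref:
    name: str

    def key(self) -> str:
        return self.name


@dataclass(frozen=True)
class Product:
    left: "ClassExpr"
    right: "ClassExpr"

    def key(self) -> str:
        return f"({self.left.key()}×{self.right.key()})"


@dataclass(frozen=True)
class UnionC:
    parts: tuple[tuple[int, "ClassExpr"], ...]

    def key(self) -> str:
        return "+".join(f"{w}·{e.key()}" for w, e in self.parts)


ClassExpr = TUnion[Neutral, Atomic, Ref, Product, UnionC]


@dataclass(frozen=True)
class AdmissibleSpec:
    """Named classes plus a distinguished root (the weighted axiom class)."""

    classes: dict[str, ClassExpr]
    root: str

    def __post_init__(self) -> None:
        for name, expr in self.classes.items():
            for ref in _refs(expr):
                if ref not in self.classes:
                    raise ValueError(f"class {name} references unknown class {ref}")
        if self.root not in self.classes:
            raise ValueError(f"root class {self.root} undefined")


def _refs(expr: ClassExpr) -> Iterable[str]:
    if isinstance(expr, Ref):
        yield expr.name
    elif isinstance(expr, Product):
        yield from _refs(expr.left)
        yield from _refs(expr.right)
    elif isinstance(expr, UnionC):
        for _, e in expr.parts:
            yield from _refs(e)


def grammar_to_spec(g: WeightedGrammar) -> AdmissibleSpec:
    """Translate an integer-weighted normal-form grammar into classes.

    Weight-1 chain nonterminals (single rule, single-symbol conclusion) are
    inlined, and textually identical conclusion classes are merged, exactly
    as in the hand-simplified specification; conclusion classes are named
    ``A1, A2, ...`` after their premise and rule position.
    """
    if g.weight_mode != "integer":
        raise ValueError("grammar_to_spec expects integer weights; reweight first")
    if any(r.weight == 0 for r in g.rules):
        raise ValueError("zero-weight rules cannot be translated")

    # chain aliases: premise with exactly one rule of weight 1 and |α| = 1
    alias: dict[str, ClassExpr] = {}
    for a in g.nonterminals:
        if a == g.axiom:
            continue
        rules = g.rules_for(a)
        if len(rules) == 1 and rules[0].weight == 1 and len(rules[0].conclusion) == 1:
            sym = rules[0].conclusion[0]
            alias[a] = Atomic(sym.name) if sym.is_terminal else Ref(sym.name)
    # resolve alias chains (loop-freeness bounds this)
    changed = True
    while changed:
        changed = False
        for a, e in list(alias.items()):
            if isinstance(e, Ref) and e.name in alias:
                alias[a] = alias[e.name]
                changed = True

    def map_symbol(sym) -> ClassExpr:
        if sym.is_terminal:
            return Atomic(sym.name)
        return alias.get(sym.name, Ref(sym.name))

    def product_of(symbols) -> ClassExpr:
        exprs = [map_symbol(s) for s in symbols]
        out = exprs[-1]
        for e in reversed(exprs[:-1]):
            out = Product(e, out)
        return out

    classes: dict[str, ClassExpr] = {}
    seen: dict[ClassExpr, str] = {}
    for a in g.nonterminals:
        if a in alias:
            continue
        parts: list[tuple[int, ClassExpr]] = []
        for k, r in enumerate(g.rules_for(a), start=1):
            expr = product_of(r.conclusion)
            if isinstance(expr, (Ref, Atomic)):
                parts.append((int(r.weight), expr))
                continue
            if expr in seen:
                name = seen[expr]
            else:
                name = f"{a}{k}"
                seen[expr] = name
                classes[name] = expr
            parts.append((int(r.weight), Ref(name)))
        classes[a] = UnionC(tuple(parts))
    return AdmissibleSpec(classes, g.axiom)


# -- exact size tables ------------------------------------------------------


class SizeTable:
    """Memoized exact sizes ``size(class, n)`` for every class of a spec."""

    def __init__(self, spec: AdmissibleSpec, fingerprint: str = ""):
        self.spec = spec
        self.fingerprint = fingerprint
        self.N = -1
        self._memo: dict[tuple[ClassExpr, int], int] = {}
        self._min = self._min_sizes()

    def _min_sizes(self) -> dict[ClassExpr, int]:
        INF = float("inf")
        m: dict[str, float] = {name: INF for name in self.spec.classes}

        def mval(expr: ClassExpr) -> float:
            if isinstance(expr, Neutral):
                return 0
            if isinstance(expr, Atomic):
                return 1
            if isinstance(expr, Ref):
                return m[expr.name]
            if isinstance(expr, Product):
                return mval(expr.left) + mval(expr.right)
            return min((mval(e) for _, e in expr.parts), default=INF)

        changed = True
        while changed:
            changed = False
            for name, expr in self.spec.classes.items():
                v = mval(expr)
                if v < m[name]:
                    m[name] = v
                    changed = True
        dead = [name for name, v in m.items() if v == INF]
        if dead:
            raise ValueError(f"non-productive classes: {dead}")
        out: dict[ClassExpr, int] = {}

        def fill(expr: ClassExpr) -> int:
            if expr in out:
                return out[expr]
            v = int(mval(expr))
            out[expr] = v
            if isinstance(expr, Product):
                fill(expr.left)
                fill(expr.right)
            elif isinstance(expr, UnionC):
                for _, e in expr.parts:
                    fill(e)
            return v

        for name, expr in self.spec.classes.items():
            out[Ref(name)] = int(m[name])
            fill(expr)
        return out

    def min_size(self, expr: ClassExpr) -> int:
        if expr not in self._min:
            if isinstance(expr, Product):
                self._min[expr] = (self.min_size(expr.left)
                                   + self.min_size(expr.right))
            elif isinstance(expr, Neutral):
                self._min[expr] = 0
            else:
                self._min[expr] = 1
        return self._min[expr]

    def ensure(self, N: int) -> None:
        """Fill all named classes up to size N (ascending, bottom-up)."""
        if N <= self.N:
            return
        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10000))
        try:
            for n in range(self.N + 1, N + 1):
                for name in self.spec.classes:
                    self._size(Ref(name), n)
            self.N = N
        finally:
            sys.setrecursionlimit(limit)

    def size(self, cls: str | ClassExpr, n: int) -> int:
        """Exact weighted number of size-n objects of the class."""
        expr = Ref(cls) if isinstance(cls, str) else cls
        if isinstance(expr, Ref) and expr.name not in self.spec.classes:
            raise KeyError(f"unknown class {expr.name!r}")
        if n < 0:
            return 0
        if n > self.N:
            self.ensure(n)
        return self._size(expr, n)

    def _size(self, expr: ClassExpr, n: int) -> int:
        key = (expr, n)
        got = self._memo.get(key)
        if got is not None:
            return got
        if isinstance(expr, Neutral):
            v = 1 if n == 0 else 0
        elif isinstance(expr, Atomic):
            v = 1 if n == 1 else 0
        elif isinstance(expr, Ref):
            v = self._size(self.spec.classes[expr.name], n)
        elif isinstance(expr, UnionC):
            v = sum(w * self._size(e, n) for w, e in expr.parts)
        else:  # Product
            lo = self.min_size(expr.left)
            hi = n - self.min_size(expr.right)
            v = 0
            for j in range(lo, hi + 1):
                a = self._size(expr.left, j)
                if a:
                    b = self._size(expr.right, n - j)
                    if b:
                        v += a * b
        self._memo[key] = v
        return v

    # -- persistence --------------------------------------------------------

    def save(self, fp: IO[str]) -> None:
        header = {"fingerprint": self.fingerprint, "N": self.N}
        fp.write(json.dumps(header) + "\n")
        for (expr, n), v in sorted(self._memo.items(),
                                   key=lambda kv: (kv[0][1], kv[0][0].key())):
            fp.write(json.dumps({"class": expr.key(), "n": n, "value": str(v)}) + "\n")

    @classmethod
    def load(cls, fp: IO[str], spec: AdmissibleSpec,
             fingerprint: str = "") -> "SizeTable":
        header = json.loads(fp.readline())
        if fingerprint and header.get("fingerprint") not in ("", fingerprint):
            raise ValueError(
                f"size table was built for grammar {header.get('fingerprint')!r}, "
                f"not {fingerprint!r}; rebuild it")
        table = cls(spec, fingerprint=header.get("fingerprint", ""))
        by_key: dict[str, ClassExpr] = {}

        def index(expr: ClassExpr) -> None:
            by_key.setdefault(expr.key(), expr)
            if isinstance(expr, Product):
                index(expr.left)
                index(expr.right)
            elif isinstance(expr, UnionC):
                for _, e in expr.parts:
                    index(e)

        for name, expr in spec.classes.items():
            index(Ref(name))
            index(expr)
        for line in fp:
            row = json.loads(line)
            expr = by_key.get(row["class"])
            if expr is not None:
                table._memo[(expr, row["n"])] = int(row["value"])
        table.N = header["N"]
        return table


def build_tables(spec: AdmissibleSpec, N: int, fingerprint: str = "") -> SizeTable:
    """Compute all class sizes for 0 <= n <= N."""
    table = SizeTable(spec, fingerprint=fingerprint)
    table.ensure(N)
    return table
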