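"""Deterministic weighted unranking and seeded random sampling.

Every class of the admissible specification carries a total order on its
size-n objects, induced by the constructions: union summands in listing
order (a class weighted by μ counts as μ consecutive copies, copy-major),
products ordered by the split size j of the left factor -- ascending
(0, 1, ..., n; "sequential") or alternating from the ends
(0, n, 1, n-1, ...; "boustrophedon") -- then left-major within a split.

``unrank_class`` maps a rank i in [0, size(class, n)) to the i-th object;
drawing i uniformly therefore samples structures with probability
proportional to their integer weight.  The boustrophedon order bounds the
number of split probes per generated structure by O(n log n); the
sequential order can need Θ(n^2) probes.
"""

from __future__ import annotations

import random
import sys
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterator, Literal

from .classes import Atomic, ClassExpr, Neutral, Product, Ref, SizeTable, UnionC
from .structures import SecondaryStructure, parse_dotbracket

Order = Literal["sequential", "boustrophedon"]


class RankError(ValueError):
    pass


@contextmanager
def _deep_recursion(n: int):
    """Allow the O(n)-deep recursion of unranking large structures."""
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 20 * n + 2000))
    try:
        yield
    finally:
        sys.setrecursionlimit(limit)


@dataclass
class Rank:
    """A 0-based rank into a (class, n) slice."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise RankError(f"rank must be >= 0, got {self.value}")


@dataclass
class SamplerConfig:
    """Sampling session: the split order, the seed, and the size tables.

    The order is fixed for the session because the two orders define
    different rank -> structure bijections.  Ranks are drawn with
    :class:`random.Random` (Mersenne Twister), whose ``randrange`` uses
    rejection sampling on blocks of random bits and is therefore unbiased
    for arbitrary-precision ranges and reproducible across platforms.
    """

    table: SizeTable
    seed: int = 0
    order: Order = "boustrophedon"
    _rng: random.Random = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.order not in ("sequential", "boustrophedon"):
            raise ValueError(f"unknown order {self.order!r}")
        self._rng = random.Random(self.seed)


def _splits(n: int, order: Order) -> Iterator[int]:
    if order == "sequential":
        yield from range(n + 1)
    else:
        for k in range((n // 2) + 1):
            yield k
            if n - k != k:
                yield n - k


class _Unranker:
    def __init__(self, table: SizeTable, order: Order):
        self.table = table
        self.order = order
        self.probes = 0

    def unrank(self, expr: ClassExpr, n: int, i: int) -> str:
        t = self.table
        if isinstance(expr, Ref):
            return self.unrank(t.spec.classes[expr.name], n, i)
        if isinstance(expr, Neutral):
            if n == 0 and i == 0:
                return ""
            raise RankError(f"neutral class has no object of size {n} rank {i}")
        if isinstance(expr, Atomic):
            if n == 1 and i == 0:
                return expr.char
            raise RankError(f"atomic class has no object of size {n} rank {i}")
        if isinstance(expr, UnionC):
            for w, part in expr.parts:
                sz = t.size(part, n)
                block = w * sz
                if i < block:
                    # copy-major: which of the w copies is discarded
                    return self.unrank(part, n, i % sz)
                i -= block
            raise RankError("rank exceeds class size")
        # Product: find the split block containing i
        left, right = expr.left, expr.right
        for j in _splits(n, self.order):
            self.probes += 1
            a = t.size(left, j)
            if not a:
                continue
            b = t.size(right, n - j)
            if not b:
                continue
            block = a * b
            if i < block:
                ia, ib = divmod(i, b)
                return self.unrank(left, j, ia) + self.unrank(right, n - j, ib)
            i -= block
        raise RankError("rank exceeds class size")


def unrank_class(table: SizeTable, cls: str | ClassExpr, n: int,
                 i: int | Rank, order: Order = "boustrophedon") -> str:
    """The object with rank ``i`` among the size-n objects of a class."""
    if isinstance(i, Rank):
        i = i.value
    expr = Ref(cls) if isinstance(cls, str) else cls
    total = table.size(expr, n)
    if not 0 <= i < total:
        raise RankError(f"rank {i} out of range [0, {total}) for size {n}")
    with _deep_recursion(n):
        return _Unranker(table, order).unrank(expr, n, i)


def count_probes(table: SizeTable, n: int, i: int,
                 order: Order = "boustrophedon",
                 cls: str | ClassExpr | None = None) -> int:
    """Number of product-split probes used to unrank rank ``i`` at size n."""
    expr = Ref(table.spec.root) if cls is None else (
        Ref(cls) if isinstance(cls, str) else cls)
    u = _Unranker(table, order)
    with _deep_recursion(n):
        u.unrank(expr, n, i)
    return u.probes


def sample(table: SizeTable, n: int, m: int,
           config: SamplerConfig) -> list[SecondaryStructure]:
    """Draw m i.i.d. structures of size n: P(s) = weight(s) / size(root, n)."""
    root = table.spec.root
    total = table.size(root, n)
    if total == 0:
        raise ValueError(f"no structures of size {n}")
    unranker = _Unranker(table, config.order)
    expr = Ref(root)
    out = []
    with _deep_recursion(n):
        for _ in range(m):
            i = config._rng.randrange(total)
            out.append(parse_dotbracket(unranker.unrank(expr, n, i), dialect="bar"))
    return out


def sample_words(table: SizeTable, n: int, m: int, config: SamplerConfig) -> list[str]:
    """Like :func:`sample` but returns raw words (skips validation)."""
    root = table.spec.root
    total = table.size(root, n)
    if total == 0:
        raise ValueError(f"no structures of size {n}")
    unranker = _Unranker(table, config.order)
    expr = Ref(root)
    with _deep_recursion(n):
        return [unranker.unrank(expr, n, config._rng.randrange(total))
                for _ in range(m)]


# -- ranking (inverse; used for round-trip checks) --------------------------


class _Ranker:
    def __init__(self, table: SizeTable, order: Order):
        self.table = table
        self.order = order
        self._derives: dict[tuple[ClassExpr, str], bool] = {}

    def derives(self, expr: ClassExpr, word: str) -> bool:
        key = (expr, word)
        got = self._derives.get(key)
        if got is not None:
            return got
        self._derives[key] = False  # provisional; unit recursion is acyclic
        if isinstance(expr, Ref):
            v = self.derives(self.table.spec.classes[expr.name], word)
        elif isinstance(expr, Neutral):
            v = word == ""
        elif isinstance(expr, Atomic):
            v = word == expr.char
        elif isinstance(expr, UnionC):
            v = any(self.derives(e, word) for _, e in expr.parts)
        else:
            v = any(self.derives(expr.left, word[:j])
                    and self.derives(expr.right, word[j:])
                    for j in range(len(word) + 1))
        self._derives[key] = v
        return v

    def rank(self, expr: ClassExpr, word: str) -> int:
        t = self.table
        n = len(word)
        if isinstance(expr, Ref):
            return self.rank(t.spec.classes[expr.name], word)
        if isinstance(expr, (Neutral, Atomic)):
            return 0
        if isinstance(expr, UnionC):
            acc = 0
            for w, part in expr.parts:
                if self.derives(part, word):
                    return acc + self.rank(part, word)  # first copy
                acc += w * t.size(part, n)
            raise ValueError(f"word {word!r} not derivable")
        acc = 0
        for j in _splits(n, self.order):
            a = t.size(expr.left, j)
            if not a:
                continue
            b = t.size(expr.right, n - j)
            if not b:
                continue
            if self.derives(expr.left, word[:j]) and self.derives(expr.right, word[j:]):
                return (acc + self.rank(expr.left, word[:j]) * b
                        + self.rank(expr.right, word[j:]))
            acc += a * b
        raise ValueError(f"word {word!r} not derivable")


def rank_structure(table: SizeTable, s: SecondaryStructure | str,
                   order: Order = "boustrophedon") -> int:
    """Rank of the first copy of ``s``: unrank(rank(s)) == s."""
    word = s.word if isinstance(s, SecondaryStructure) else s
    table.ensure(len(word))
    ranker = _Ranker(table, order)
    root = Ref(table.spec.root)
    with _deep_recursion(len(word)):
        if not ranker.derives(root, word):
            raise ValueError(f"{word!r} is not in the language of the specification")
        return ranker.rank(root, word)
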