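"""Dot-bracket secondary structures: parsing, enumeration, motif decomposition.

The canonical encoding is the bar-bracket dialect: ``|`` for an unpaired
base, ``(`` ``)`` for a base pair.  The Vienna dot dialect (``.`` for
unpaired) is accepted on input and converted.  A valid structure is a
balanced, non-crossing word in which every hairpin loop contains at least
three unpaired bases and at least one pair exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

MIN_HAIRPIN = 3
ORACLE_BOUND = 16


class StructureError(ValueError):
    """Raised for words that are not valid secondary structures."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        super().__init__(message if position is None
                         else f"position {position}: {message}")


@dataclass(frozen=True)
class SecondaryStructure:
    """A validated bar-bracket word with its pairing table.

    ``pairs`` lists (open, close) index pairs, 0-based, sorted by the opening
    position.  Instances are created through :func:`parse_dotbracket`.
    """

    word: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.word)

    def partner_table(self) -> list[int]:
        """partner[i] = index paired with i, or -1 if i is unpaired."""
        partner = [-1] * len(self.word)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def render(self, dialect: Literal["bar", "dot"] = "bar") -> str:
        if dialect == "bar":
            return self.word
        if dialect == "dot":
            return self.word.replace("|", ".")
        raise ValueError(f"unknown dialect {dialect!r}")

    def __str__(self) -> str:
        return self.word

    def __len__(self) -> int:
        return len(self.word)


def parse_dotbracket(text: str,
                     dialect: Literal["bar", "dot", "auto"] = "auto",
                     ) -> SecondaryStructure:
    """Parse one dot-bracket line into a validated structure.

    The first offending position is reported on error: unbalanced or crossing
    brackets, foreign characters, a hairpin shorter than three bases, or a
    word without any pair.
    """
    word = text.strip()
    if not word:
        raise StructureError("empty structure line")
    if dialect == "dot" or (dialect == "auto" and "." in word):
        if "|" in word and "." in word:
            raise StructureError("structure mixes '.' and '|' dialects")
        word = word.replace(".", "|")
    stack: list[tuple[int, int, bool]] = []  # (open position, bars inside, saw inner pair)
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(word):
        if ch == "|":
            if stack:
                i, bars, inner = stack[-1]
                stack[-1] = (i, bars + 1, inner)
        elif ch == "(":
            stack.append((pos, 0, False))
        elif ch == ")":
            if not stack:
                raise StructureError("unmatched ')'", pos)
            i, bars, inner = stack.pop()
            if not inner and bars < MIN_HAIRPIN:
                raise StructureError(
                    f"hairpin of size {bars} violates minimum {MIN_HAIRPIN}", pos)
            pairs.append((i, pos))
            if stack:
                k, b, _ = stack[-1]
                stack[-1] = (k, b, True)
        else:
            raise StructureError(f"foreign character {ch!r}", pos)
    if stack:
        raise StructureError("unmatched '('", stack[-1][0])
    if not pairs:
        raise StructureError("completely unpaired structures are excluded")
    pairs.sort()
    return SecondaryStructure(word, tuple(pairs))


def is_valid(text: str, dialect: Literal["bar", "dot", "auto"] = "auto") -> bool:
    try:
        parse_dotbracket(text, dialect)
        return True
    except StructureError:
        return False


def enumerate_language(n: int, bound: int = ORACLE_BOUND) -> list[SecondaryStructure]:
    """All valid structures of size n, in lexicographic word order.

    Exhaustive oracle with branch pruning on bracket balance and the hairpin
    constraint; refuses n above ``bound`` to guard against exponential
    blowup.  Lexicographic order follows the character order '(' < ')' < '|'
    (plain string order on the bar-bracket alphabet).
    """
    if n > bound:
        raise ValueError(f"n={n} exceeds the enumeration oracle bound {bound}")
    out: list[SecondaryStructure] = []
    word: list[str] = []

    # stack entries: [bars inside, saw inner pair]; characters tried in the
    # order '(' < ')' < '|' so output is already lexicographically sorted
    def rec(pos: int, stack: list[list[int]], npairs: int) -> None:
        if pos == n:
            if not stack and npairs > 0:
                w = "".join(word)
                out.append(SecondaryStructure(w, _pairs_of(w)))
            return
        remaining = n - pos
        if len(stack) > remaining:
            return
        # '('
        if len(stack) + 1 <= remaining - 1:
            word.append("(")
            stack.append([0, 0])
            rec(pos + 1, stack, npairs)
            stack.pop()
            word.pop()
        # ')'
        if stack:
            bars, inner = stack[-1]
            if inner or bars >= MIN_HAIRPIN:
                top = stack.pop()
                saved = stack[-1][1] if stack else None
                if stack:
                    stack[-1][1] = 1
                word.append(")")
                rec(pos + 1, stack, npairs + 1)
                word.pop()
                if stack:
                    stack[-1][1] = saved
                stack.append(top)
        # '|'
        word.append("|")
        if stack:
            stack[-1][0] += 1
        rec(pos + 1, stack, npairs)
        if stack:
            stack[-1][0] -= 1
        word.pop()

    rec(0, [], 0)
    return out


def _pairs_of(word: str) -> tuple[tuple[int, int], ...]:
    stack, pairs = [], []
    for pos, ch in enumerate(word):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.append((stack.pop(), pos))
    pairs.sort()
    return tuple(pairs)


# ---------------------------------------------------------------------------
# motif decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifInstances:
    """Per-instance motif statistics of one structure.

    Each list holds one entry per motif instance, so pooled means and
    variances over a sample can be computed without re-walking structures.
    """

    hairpin_bars: tuple[int, ...]          # unpaired bases per hairpin loop
    bulge_bars: tuple[int, ...]            # unpaired bases per bulge loop
    interior_bars: tuple[int, ...]         # unpaired bases per interior loop
    multiloop_bars: tuple[int, ...]        # unpaired bases per multiloop
    multiloop_branches: tuple[int, ...]    # inner helices per multiloop
    helix_pairs: tuple[int, ...]           # base pairs per helix
    exterior_bars: int                     # unpaired bases in the exterior loop
    exterior_helices: int                  # helices adjacent to the exterior loop
    num_stacked: int                       # pairs closing a stacked pair
    unpaired_runs: int                     # maximal runs of unpaired bases


@dataclass(frozen=True)
class MotifProfile:
    """Structural-motif counts of a single secondary structure.

    Conservation laws: every unpaired base lies in exactly one loop
    (``num_unp = unp_e + unp_h + unp_b + unp_i + unp_m``) and every pair
    closes exactly one loop type
    (``num_bps = num_s + num_h + num_b + num_i + num_m``).
    """

    num_unp: int
    num_bps: int
    num_urs: int
    num_e: int
    num_h: int
    num_s: int
    num_b: int
    num_i: int
    num_m: int
    num_hel: int
    unp_e: int
    unp_h: int
    unp_b: int
    unp_i: int
    unp_m: int
    bps_e: int
    bps_m: int
    bps_hel: int


def motif_instances(s: SecondaryStructure) -> MotifInstances:
    """Walk the pairing table and classify every loop.

    A pair with exactly one directly nested pair closes a stacked pair when
    the nesting is immediate on both sides, a bulge when exactly one side
    has unpaired bases, and an interior loop when both sides do; a pair with
    two or more directly nested pairs closes a multiloop and one with none a
    hairpin.  A helix is a maximal chain of stacked pairs plus its terminal
    pair (an isolated pair is a helix of one pair).
    """
    word = s.word
    n = len(word)
    partner = s.partner_table()

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        """Directly nested pairs and unpaired-base count strictly inside (i, j)."""
        kids, bars = [], 0
        k = i + 1
        while k < j:
            if partner[k] >= 0:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                bars += 1
                k += 1
        return kids, bars

    hairpin_bars: list[int] = []
    bulge_bars: list[int] = []
    interior_bars: list[int] = []
    multiloop_bars: list[int] = []
    multiloop_branches: list[int] = []
    helix_pairs: list[int] = []
    num_stacked = 0

    # top level (exterior loop)
    top_children, exterior_bars = children_of(-1, n)
    exterior_helices = len(top_children)

    stack = list(top_children)
    helix_run = {}  # opening pos of a pair -> pairs accumulated in its helix so far
    for i, j in top_children:
        helix_run[i] = 1
    while stack:
        i, j = stack.pop()
        kids, bars = children_of(i, j)
        run = helix_run.pop(i)
        if len(kids) == 1:
            (k, l) = kids[0]
            if k == i + 1 and l == j - 1:
                num_stacked += 1
                helix_run[k] = run + 1
            else:
                helix_pairs.append(run)
                helix_run[k] = 1
                left = k - i - 1
                right = j - l - 1
                if left and right:
                    interior_bars.append(bars)
                else:
                    bulge_bars.append(bars)
            stack.append(kids[0])
        elif not kids:
            helix_pairs.append(run)
            hairpin_bars.append(bars)
        else:
            helix_pairs.append(run)
            multiloop_bars.append(bars)
            multiloop_branches.append(len(kids))
            for k, l in kids:
                helix_run[k] = 1
                stack.append((k, l))

    runs = 0
    prev_bar = False
    for ch in word:
        bar = ch == "|"
        if bar and not prev_bar:
            runs += 1
        prev_bar = bar

    return MotifInstances(
        hairpin_bars=tuple(hairpin_bars),
        bulge_bars=tuple(bulge_bars),
        interior_bars=tuple(interior_bars),
        multiloop_bars=tuple(multiloop_bars),
        multiloop_branches=tuple(multiloop_branches),
        helix_pairs=tuple(helix_pairs),
        exterior_bars=exterior_bars,
        exterior_helices=exterior_helices,
        num_stacked=num_stacked,
        unpaired_runs=runs,
    )


def decompose_motifs(s: SecondaryStructure) -> MotifProfile:
    """Aggregate the motif instances of ``s`` into a per-structure profile."""
    m = motif_instances(s)
    num_h = len(m.hairpin_bars)
    num_b = len(m.bulge_bars)
    num_i = len(m.interior_bars)
    num_m = len(m.multiloop_bars)
    num_unp = (m.exterior_bars + sum(m.hairpin_bars) + sum(m.bulge_bars)
               + sum(m.interior_bars) + sum(m.multiloop_bars))
    num_bps = len(s.pairs)
    return MotifProfile(
        num_unp=num_unp,
        num_bps=num_bps,
        num_urs=m.unpaired_runs,
        num_e=1,
        num_h=num_h,
        num_s=m.num_stacked,
        num_b=num_b,
        num_i=num_i,
        num_m=num_m,
        num_hel=len(m.helix_pairs),
        unp_e=m.exterior_bars,
        unp_h=sum(m.hairpin_bars),
        unp_b=sum(m.bulge_bars),
        unp_i=sum(m.interior_bars),
        unp_m=sum(m.multiloop_bars),
        bps_e=m.exterior_helices,
        bps_m=sum(m.multiloop_branches),
        bps_hel=sum(m.helix_pairs),
    )
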