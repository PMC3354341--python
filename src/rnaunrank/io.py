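"""Structure-database files and synthetic fixture generation.

Structure files are plain text: one dot-bracket structure per line, lines
starting with ``>`` or ``#`` ignored.  Both the bar dialect (``|()``) and
the Vienna dot dialect (``.()``) are accepted; the dialect is auto-detected
per file and may not be mixed within one file.

The fixture generator emulates a structure database by sampling a known
SCFG through the full pipeline, so training and parameter-recovery
experiments are testable without any external data.  Its default size
profile (2500 structures at each of the sizes 100, 150, 200 and 250;
10,000 in total) spans the tRNA-to-rRNA-fragment scale at which every
structural motif of the model occurs in quantity.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .grammars import WeightedGrammar
from .pipeline import StructureSampler
from .structures import SecondaryStructure, StructureError, parse_dotbracket

logger = logging.getLogger(__name__)

DEFAULT_FIXTURE_SIZES: tuple[tuple[int, int], ...] = (
    (100, 2500), (150, 2500), (200, 2500), (250, 2500),
)


def sample_from_scfg(g: WeightedGrammar, m: int, seed: int,
                     max_size: int = 50_000) -> list[SecondaryStructure]:
    """Draw m structures from a consistent SCFG, sizes distributed as the
    grammar dictates.

    This is plain stochastic derivation: starting from the axiom, each
    nonterminal is replaced by a rule drawn according to its probability
    (exact integer thresholds over the premise's common denominator, so no
    floating point enters the choice).  Unlike fixed-size unranking this
    reproduces the grammar's own size distribution, which is what a
    training database looks like; relative-frequency training on such a
    sample is a consistent estimator of the rule probabilities.

    Derivations longer than ``max_size`` (vanishingly rare for a trained
    model whose mean size is a few hundred) are rejected and redrawn.
    """
    from fractions import Fraction
    from math import lcm

    if not g.stochastic:
        raise ValueError("sample_from_scfg requires a stochastic grammar")
    thresholds: dict[str, tuple[int, list[tuple[int, object]]]] = {}
    for a in g.nonterminals:
        rules = g.rules_for(a)
        D = lcm(*(Fraction(r.weight).denominator for r in rules))
        acc, table = 0, []
        for r in rules:
            acc += int(Fraction(r.weight) * D)
            table.append((acc, r))
        thresholds[a] = (D, table)

    rng = random.Random(seed)
    out: list[SecondaryStructure] = []
    while len(out) < m:
        # leftmost derivation via an explicit stack of pending symbols
        stack = [("nt", g.axiom)]
        chars: list[str] = []
        while stack and len(chars) <= max_size:
            kind, name = stack.pop()
            if kind == "t":
                chars.append(name)
                continue
            D, table = thresholds[name]
            x = rng.randrange(D)
            for acc, r in table:
                if x < acc:
                    break
            for s in reversed(r.conclusion):
                stack.append(("t", s.name) if s.is_terminal else ("nt", s.name))
        if stack:  # runaway derivation rejected
            continue
        out.append(parse_dotbracket("".join(chars), dialect="bar"))
    return out


@dataclass
class DbReadError(Exception):
    errors: list[tuple[int, str]]

    def __str__(self) -> str:
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        return f"invalid structures in database: {lines}{more}"


def read_structure_db(path: str | Path, strict: bool = False
                      ) -> list[SecondaryStructure]:
    """Read and validate a structure database file.

    Invalid lines are collected and logged with their line numbers; in
    strict mode any invalid line aborts with :class:`DbReadError`.
    """
    path = Path(path)
    text = path.read_text()
    has_dot = "." in text
    has_bar = "|" in text
    if has_dot and has_bar:
        raise DbReadError([(0, "file mixes '.' and '|' dialects")])
    dialect = "dot" if has_dot else "bar"
    out: list[SecondaryStructure] = []
    errors: list[tuple[int, str]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith((">", "#")):
            continue
        try:
            out.append(parse_dotbracket(line, dialect))
        except StructureError as exc:
            errors.append((ln, str(exc)))
    if errors:
        if strict:
            raise DbReadError(errors)
        for ln, msg in errors:
            logger.warning("%s line %d skipped: %s", path.name, ln, msg)
    return out


def write_structure_db(path: str | Path, structures: Sequence[SecondaryStructure],
                       dialect: str = "bar", header: str | None = None) -> None:
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.extend(s.render(dialect) for s in structures)
    path.write_text("\n".join(lines) + "\n")


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure database drawn from a known SCFG.

    With ``sizes=None`` (the default) the database holds ``count``
    structures whose sizes follow the grammar's own size distribution
    (stochastic derivation); this is the mode used for parameter-recovery
    experiments, where the estimator must see the unconditional model.  A
    ``sizes`` list of (size, count) pairs instead draws fixed-size samples
    through the weighted-unranking pipeline.
    """

    grammar: WeightedGrammar
    sizes: tuple[tuple[int, int], ...] | None = None
    count: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sizes is not None:
            for n, count in self.sizes:
                if n < 5:
                    raise ValueError(f"fixture size {n} below the minimal structure size 5")
                if count < 1:
                    raise ValueError(f"fixture count {count} must be >= 1")
        elif self.count < 1:
            raise ValueError("fixture count must be >= 1")


def generate_fixture_db(fx: FixtureSpec, path: str | Path | None = None,
                        sampler: StructureSampler | None = None
                        ) -> list[SecondaryStructure]:
    """Sample a synthetic database; deterministic for a given seed.

    For fixed-size recipes an existing :class:`StructureSampler` for the
    same grammar can be passed to reuse its size tables; its RNG state is
    not used (a fresh seeded configuration is created so output depends
    only on ``fx``).
    """
    if fx.sizes is None:
        structures = sample_from_scfg(fx.grammar, fx.count, fx.seed)
    else:
        if sampler is None:
            sampler = StructureSampler.from_grammar(fx.grammar, seed=fx.seed)
        else:
            from .unranking import SamplerConfig
            sampler = StructureSampler(
                sampler.grammar, sampler.rnf_report, sampler.reweight_report,
                sampler.spec, sampler.table,
                SamplerConfig(table=sampler.table, seed=fx.seed,
                              order=sampler.config.order))
        structures = sampler.sample_sizes(fx.sizes)
    if path is not None:
        desc = (f"count={fx.count}" if fx.sizes is None
                else f"sizes={list(fx.sizes)}")
        write_structure_db(path, structures,
                           header=f"synthetic fixture: seed={fx.seed} {desc}")
    return structures
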