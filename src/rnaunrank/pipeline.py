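"""End-to-end sampling pipeline.

Ties together training, normal-form transformation, integer reweighting,
class-size tables and weighted unranking behind one object, logging the
artifacts (grammar fingerprints, scaling constants, table extent) needed to
reproduce any sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .classes import AdmissibleSpec, SizeTable, build_tables, grammar_to_spec
from .grammars import WeightedGrammar, load_builtin
from .reweight import ReweightReport, prepare_integer_grammar
from .rnf import RnfReport, to_rnf
from .structures import SecondaryStructure
from .unranking import Order, SamplerConfig, sample

logger = logging.getLogger(__name__)


@dataclass
class StructureSampler:
    """A ready-to-sample weighted unranking pipeline for one grammar."""

    grammar: WeightedGrammar
    rnf_report: RnfReport
    reweight_report: ReweightReport
    spec: AdmissibleSpec
    table: SizeTable
    config: SamplerConfig

    @classmethod
    def from_grammar(cls, g: WeightedGrammar, *, digits: int | None = 4,
                     seed: int = 0, order: Order = "boustrophedon",
                     table: SizeTable | None = None) -> "StructureSampler":
        rnf_report = to_rnf(g)
        rw = prepare_integer_grammar(rnf_report.result, digits=digits)
        spec = grammar_to_spec(rw.result)
        if table is None:
            table = SizeTable(spec, fingerprint=rw.result.fingerprint())
        logger.info(
            "pipeline ready: grammar=%s fp=%s -> rnf %d rules -> s=%d c=%d "
            "digits=%s -> %d classes",
            g.name or "anonymous", g.fingerprint(), len(rnf_report.result.rules),
            rw.s, rw.c, rw.digits, len(spec.classes))
        return cls(g, rnf_report, rw, spec, table,
                   SamplerConfig(table=table, seed=seed, order=order))

    @classmethod
    def default(cls, *, seed: int = 0,
                order: Order = "boustrophedon") -> "StructureSampler":
        """Pipeline for the bundled rRNA-trained structure-motif model."""
        return cls.from_grammar(load_builtin("Gsto_hat"), seed=seed, order=order)

    def ensure(self, n: int) -> None:
        if n > self.table.N:
            self.table.ensure(n)
            logger.info("size tables extended to N=%d (fingerprint %s)",
                        self.table.N, self.table.fingerprint)

    def count(self, n: int) -> int:
        """Weighted class size of all structures of size n."""
        self.ensure(n)
        return self.table.size(self.spec.root, n)

    def sample(self, n: int, m: int) -> list[SecondaryStructure]:
        self.ensure(n)
        logger.info("sampling m=%d structures at n=%d (seed=%d order=%s)",
                    m, n, self.config.seed, self.config.order)
        return sample(self.table, n, m, self.config)

    def sample_sizes(self, sizes: Sequence[tuple[int, int]]
                     ) -> list[SecondaryStructure]:
        """Sample count structures for each (size, count), in order."""
        self.ensure(max(n for n, _ in sizes))
        out: list[SecondaryStructure] = []
        for n, count in sizes:
            out.extend(sample(self.table, n, count, self.config))
        return out
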