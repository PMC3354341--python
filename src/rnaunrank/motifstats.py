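"""Expectation/variance summaries of structural-motif parameters.

For a sample of structures the summary reports, per parameter, the mean and
the population variance: per-structure counters (num_*) are averaged over
structures, per-motif quantities (unp_*, bps_*) over motif instances pooled
across the whole sample.  Parameters that are structurally constant or
undefined (unpaired bases of a stacked pair, helix count of a hairpin) are
reported as missing, mirroring the dashes of the reference table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .structures import SecondaryStructure, decompose_motifs, motif_instances
from .unranking import SamplerConfig, sample

logger = logging.getLogger(__name__)

PARAMETERS = [
    "num_unp", "num_bps", "num_urs",
    "num_e", "num_h", "num_s", "num_b", "num_i", "num_m", "num_hel",
    "unp_e", "unp_h", "unp_s", "unp_b", "unp_i", "unp_m", "unp_hel",
    "bps_e", "bps_h", "bps_s", "bps_b", "bps_i", "bps_m", "bps_hel",
]

_NUM_FIELDS = ["num_unp", "num_bps", "num_urs", "num_e", "num_h", "num_s",
               "num_b", "num_i", "num_m", "num_hel"]


@dataclass
class SummaryTable:
    """Per-parameter mean and population variance over a sample."""

    means: dict[str, float | None]
    variances: dict[str, float | None]
    sample_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": [self.means[p] for p in PARAMETERS],
             "variance": [self.variances[p] for p in PARAMETERS]},
            index=pd.Index(PARAMETERS, name="parameter"),
        )

    def to_tsv(self) -> str:
        df = self.to_frame()
        return df.to_csv(sep="\t", na_rep="--")

    @staticmethod
    def compare_frame(native: "SummaryTable", random_: "SummaryTable") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "random_mean": [random_.means[p] for p in PARAMETERS],
                "native_mean": [native.means[p] for p in PARAMETERS],
                "random_variance": [random_.variances[p] for p in PARAMETERS],
                "native_variance": [native.variances[p] for p in PARAMETERS],
            },
            index=pd.Index(PARAMETERS, name="parameter"),
        )


def _mean_var(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var


def summarize(sample_: Sequence[SecondaryStructure],
              per_structure_means: bool = False) -> SummaryTable:
    """Summary of motif parameters over a nonempty sample.

    With ``per_structure_means=True`` the per-motif parameters are averaged
    within each structure first and those averages averaged over structures
    (an alternative reading of pooled per-motif statistics); the default
    pools all motif instances of the sample.
    """
    if not sample_:
        raise ValueError("cannot summarize an empty sample")
    profiles = [decompose_motifs(s) for s in sample_]
    instances = [motif_instances(s) for s in sample_]

    means: dict[str, float | None] = {}
    variances: dict[str, float | None] = {}
    for p in _NUM_FIELDS:
        means[p], variances[p] = _mean_var([getattr(pr, p) for pr in profiles])

    def pooled(lists: Sequence[Sequence[float]]) -> tuple[float | None, float | None]:
        if per_structure_means:
            per_struct = [sum(l) / len(l) for l in lists if l]
            return _mean_var(per_struct)
        flat = [v for l in lists for v in l]
        return _mean_var(flat)

    means["unp_e"], variances["unp_e"] = _mean_var([m.exterior_bars for m in instances])
    means["unp_h"], variances["unp_h"] = pooled([m.hairpin_bars for m in instances])
    means["unp_b"], variances["unp_b"] = pooled([m.bulge_bars for m in instances])
    means["unp_i"], variances["unp_i"] = pooled([m.interior_bars for m in instances])
    means["unp_m"], variances["unp_m"] = pooled([m.multiloop_bars for m in instances])
    means["unp_s"] = variances["unp_s"] = None      # stacked pairs have no unpaired bases
    means["unp_hel"] = variances["unp_hel"] = None  # likewise helices

    means["bps_e"], variances["bps_e"] = _mean_var([m.exterior_helices for m in instances])
    means["bps_h"] = variances["bps_h"] = None      # a hairpin contains no further pairs
    # each stacked pair / bulge / interior loop is closed by exactly one pair
    for p, count in (("bps_s", sum(pr.num_s for pr in profiles)),
                     ("bps_b", sum(pr.num_b for pr in profiles)),
                     ("bps_i", sum(pr.num_i for pr in profiles))):
        means[p], variances[p] = (1.0, 0.0) if count else (None, None)
    means["bps_m"], variances["bps_m"] = pooled(
        [m.multiloop_branches for m in instances])
    means["bps_hel"], variances["bps_hel"] = pooled(
        [m.helix_pairs for m in instances])
    return SummaryTable(means, variances, len(sample_))


def size_matched_sample(db: Sequence[SecondaryStructure],
                        table, config: SamplerConfig
                        ) -> list[SecondaryStructure]:
    """One random structure of size n per native structure of size n.

    Native structures below the minimal structure size are skipped with a
    warning; the result therefore matches the native multiset of admissible
    sizes exactly.
    """
    out: list[SecondaryStructure] = []
    for s in db:
        n = len(s)
        if table.size(table.spec.root, n) == 0:
            logger.warning("no structures of size %d exist; skipping a native entry", n)
            continue
        out.extend(sample(table, n, 1, config))
    return out
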