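"""Compare motif statistics of a 'native' sample against matched random ones.

Uses a sample drawn from the model as a stand-in for a native database,
draws one random structure of the same size for each entry, and prints the
two-sided summary: per-structure motif counts (hairpins, stacked pairs,
bulges, interior loops, multiloops, helices) and pooled per-motif averages.
Because both samples come from the same model here, the columns agree up to
sampling noise; with a real database the comparison quantifies how
realistic the sampler's output is.
"""

from rnaunrank import StructureSampler, SummaryTable, size_matched_sample, summarize
from rnaunrank.unranking import SamplerConfig

sampler = StructureSampler.default(seed=5)
native = sampler.sample(60, 150) + sampler.sample(80, 150)

random_matched = size_matched_sample(
    native, sampler.table, SamplerConfig(table=sampler.table, seed=99))

frame = SummaryTable.compare_frame(summarize(native), summarize(random_matched))
print(frame.round(3).fillna("--"))
print(f"\n({len(native)} structures per column; '--' marks parameters that "
      "are undefined or constant by construction)")
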