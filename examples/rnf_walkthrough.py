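"""Walk through the grammar transformation pipeline step by step.

Starts from the 54-rule structure-motif SCFG with its exact trained
probabilities and shows what each stage produces: the derivation chains
collapsed by the normal-form transformation, the census of rules created
and removed, the common denominators of the rounded weights, and a few of
the resulting integer weights.
"""

from rnaunrank import load_builtin, to_rnf
from rnaunrank.reweight import common_denominators, reweight, round_weights

g = load_builtin("Gsto_hat")
print(f"input: {g!r}")

report = to_rnf(g)
print(f"\nstep 1: removed {len(report.removed_unit_rules)} unit rules, "
      f"gathered {len(report.chains)} chains, e.g.")
for chain in report.chains.targets["T"]:
    print(f"   {chain.source} => {chain.target.name:2s} via {''.join(chain.via) or '-':3s}"
          f"  weight {chain.weight}")
print(f"step 2: added {len(report.chain_rules)} weight-1 chain rules")
print(f"step 3: substitution produced {len(report.substituted_rules)} rules")
print(f"step 4: removed symbols {sorted(report.dead_symbols)} "
      f"and {len(report.dead_rules)} rules; "
      f"{len(report.result.rules) - len(report.chain_rules)} main rules remain")

rounded = round_weights(report.result, 4)
s, c = common_denominators(rounded)
print(f"\nrounded to 4 decimals; common denominators s={s}, c={c}")

integer = reweight(rounded).result
print("integer weights scale each rule by c^(length-1); for example:")
for rid in (1, 15, 32):
    r = integer.rule(rid)
    print(f"   rule {rid:3d}  {r.premise} -> "
          f"{' '.join(sym.name for sym in r.conclusion):14s} weight {r.weight}")
print("\nRelative weights of same-size structures are exactly preserved.")
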