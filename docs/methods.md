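# Methods

## Model

The package samples pseudoknot-free RNA secondary structures of a fixed
size n from the distribution induced by a stochastic context-free grammar.
Structures are abstracted from sequence: a word over the alphabet
{`(`, `)`, `|`} encodes one unpaired base per bar and one base pair per
matching bracket pair.  The language L of admissible words is defined by
three constraints: brackets balance and nest (no pseudoknots), every
innermost pair encloses at least three unpaired bases (the steric
minimum-hairpin constraint), and completely unpaired words are excluded.

The bundled default model is an unambiguous, ε-free, loop-free SCFG with
26 nonterminals and 54 rules whose nonterminals correspond to structural
motifs (exterior loop strands, helix initiation, stacked pair, bulge
left/right, 1×1…2×2 and general interior loops, multiloop branches,
hairpin strands).  Every rule carries an exact rational probability -- the
relative frequency of the rule among the leftmost derivations of an
SSU/LSU rRNA secondary-structure database, shipped as exact
numerator/denominator pairs.  Per premise the probabilities sum to exactly
1; the consistency check uses `fractions.Fraction` and has no tolerance
parameter.  Unambiguity is not proven symbolically here; it is checked
empirically: the number of derivation trees per length, computed by
dynamic programming with all weights set to 1, equals the exhaustive count
of the language for all n ≤ 12 (tests), and the derivation counts satisfy
the structure-generating-function polynomial identity coefficient-wise up
to degree 20.

## Pipeline

**Normal form.**  Unranking requires every step of a derivation to grow
the word, so non-lengthening (unit) rules are eliminated first.  All unit
derivation chains A ⇒ A₁ ⇒ … ⇒ X from non-axiom nonterminals are
collected; each becomes a fresh nonterminal `A_{X,via}` with the single
weight-1 rule `A_{X,via} → X`, where `via` spells the intermediate
symbols.  Each surviving rule is replaced by the full set of substitution
variants (every combination of chain substitutions across the occurrences
in its conclusion), with weights multiplied by the chain weights.
Nonterminals left without rules, and rules mentioning them, are removed.
For the bundled grammar: 22 unit rules removed, 32 chains, 32 chain rules,
79 substituted rules, dead symbols {T, L, N, Y}, 6 dead rules, 73
surviving main rules.  Word weights are preserved exactly (verified
against brute-force derivation weights for all words up to size 9).

Two listing conventions are pinned down because rule ids define all
downstream tie-breaking: chains are enumerated per source by length, with
terminal-target chains before nonterminal-target ones within a length;
substitution variants are enumerated mixed-radix over the conclusion's
occurrences with the occurrence having the most chains varying fastest
(ties: leftmost first).  These conventions reproduce the published listing
of the transformed grammar rule-for-rule; all table comparisons in the
test suite additionally match rules by content so that no numeric result
depends on the convention.

**Integer reweighting.**  Rational weights are rounded to `digits`
decimals (default 4), stored as exact rationals.  Rounding is
half-away-from-zero -- the rule is inferred from the published rounded
tables and pinned by golden tests.  A weight that would round to zero
would silently delete words, so the precision escalates grammar-wide until
all rounded weights are positive.  With s the least common denominator of
the axiom-rule weights and c that of all others (both 10000 at 4 decimals),
every rule A → α receives μ = λ·c^(|α|−1) (axiom: μ = λ·s).  Since a rule
lengthens the sentential form by |α|−1 and the normal form guarantees
length-1 non-axiom rules have integral weights, every μ is a positive
integer and every word w of size n carries weight s·c^(n−1)·λ(w): the
distribution conditioned on size is exactly that of the rounded SCFG.  An
exact mode (`digits=None`) skips rounding and uses the true least common
denominators; for trained grammars these are astronomically large, so the
mode exists for small grammars and tests.

**Weighted classes and counting.**  The integer-weighted grammar is read
as an admissible specification: terminals become atomic classes,
conclusions become right-associated binary cartesian products, and each
nonterminal becomes a weighted disjoint union of its conclusion classes
(weighting by μ = formal μ-fold replication).  Weight-1 chain nonterminals
are inlined and textually identical conclusion classes merged, as in the
hand-simplified published specification; association direction and merge
order are fixed globally because they are part of the canonical object
order.  Class sizes follow the standard recursion (union: weighted sum;
product: convolution) with memoized arbitrary-precision integers; the
convolution range is restricted by each factor's minimal object size,
which both prunes zero terms and guarantees termination.  Building tables
to N costs O(N²) coefficient operations (about 4 s to N = 300 on one
core); tables persist as JSON-lines stamped with a grammar fingerprint so
stale tables are refused on reload.

**Unranking and sampling.**  The constructions induce a total order:
union summands in listing order, with the μ copies of a weighted class
copy-major (copy index = rank div class size, discarded on output);
products ordered by the left factor's size j -- ascending for the
sequential order, alternating 0, n, 1, n−1, … for the boustrophedon
order -- then left-major within a split.  Ranks are 0-based.  Unranking
locates the union summand by cumulative weighted sizes and the product
split by scanning blocks in the chosen order; the boustrophedon scan makes
the per-structure work grow as n·log n (verified by a seeded doubling
experiment on probe counts at n = 64…256), whereas the sequential order is
quadratic on adversarial ranks.  Sampling draws ranks uniformly with
`random.Random.randrange`, which performs rejection sampling on blocks of
random bits and is unbiased for arbitrary-precision ranges; the generator
and seed are recorded so every sample is reproducible.  A ranking inverse
(minimal rank of a structure) exists for round-trip testing.

## Training and synthetic data

Because the grammar is unambiguous, each structure has a unique leftmost
derivation.  The default derivation extractor is a motif-directed
decomposer that walks the pairing table and emits the rule multiset in
time linear in the structure size (rRNA-scale structures train in
milliseconds); a generic chart parser over arbitrary grammars serves as
its cross-validation oracle on all structures up to size 12.  Training
sets each rule's weight to (count + pseudocount)/(premise total +
pseudocount·rules-of-premise) as an exact rational; the default
pseudocount is 0, and premises never observed fall back to the uniform
distribution with a logged warning so the result is always a valid SCFG.
Duplicates count with multiplicity.  A subsample-stability analysis
retrains on seeded random fractions of the database and reports per-rule
population variances.

The synthetic-data generator emulates a structure database in two modes.
The default draws structures by plain stochastic derivation from the
grammar (exact integer thresholds per premise), so sizes follow the
model's own size distribution -- under the bundled model the mean size is
roughly 1,700 with a long tail, matching its rRNA provenance.  This is the
mode used for parameter recovery: relative-frequency training on
unconditional samples is a consistent estimator, and 10,000 structures
recover every rule probability with usage ≥ 50 to within about ±0.004,
comfortably inside the ±0.02 test band.  The alternative mode draws
fixed-size samples through the unranking pipeline, which is a draw from
the size-*conditioned* distribution: its rule-usage frequencies are tilted
away from the unconditional probabilities (measured bias up to 0.5 at
n = 60 on the exterior-loop and multiloop continuation rules, decaying
roughly like 1/n), so fixed-size fixtures are suitable for distributional
tests at fixed n but not for recovering unconditional probabilities.  What
passing tests show is therefore internal consistency of the
model-transformation-sampling loop; they cannot certify how well the
bundled probabilities describe any particular real RNA family, which
depends on the original training database.

## Motif statistics

The evaluation module classifies every base pair as closing exactly one of
hairpin, stacked pair, bulge, interior loop or multiloop: a pair with one
directly nested pair closes a stacked pair if the nesting is immediate on
both sides, a bulge if exactly one side has unpaired bases and an interior
loop if both do; two or more nested pairs close a multiloop, none a
hairpin.  A helix is a maximal chain of stacked pairs plus its terminal
pair.  Two conservation laws hold for every structure and are asserted
exhaustively in tests: every unpaired base lies in exactly one loop, and
every pair closes exactly one loop.  Summaries report per-structure means
and population variances for the counters and pooled per-motif-instance
statistics for unpaired/pair-adjacency parameters; because the published
table does not state whether its per-motif rows are instance-pooled or
per-structure expectations, both readings are available
(`per_structure_means=True`), with instance pooling as the default.
Structurally constant or undefined parameters (unpaired bases per stacked
pair, pairs inside a hairpin) are reported as missing.  The
native-versus-random comparison draws one random structure per native size
("size-matched" sampling).

## Problem sizes and numerical choices

Default test and experiment scales, chosen once: exhaustive oracles run to
size 12 (the enumeration oracle itself is capped at 16); word-equivalence
and distribution-preservation checks use brute-force derivation weights to
sizes 8-10; the goodness-of-fit experiment draws 50,000 samples at n = 10
and pools chi-square cells with expected count < 5; parameter recovery
uses 10,000 unconditional structures; the probe-count doubling experiment
runs at n = 64, 128, 256.  All randomness flows through named integer
seeds.  Ties in rounding go away from zero; ranks are 0-based; rule ids
are 1-based listing positions and break all ordering ties.

## Known limitations

Free-energy models, energy-based rejection sampling and the associated
hypothesis tests are out of scope (their parameters are not part of this
package's data).  Pseudoknots, nucleotide sequences and CT/BPSEQ formats
are not modeled.  Unambiguity of user-supplied grammars is not verified
symbolically; training and sampling assume it, and the derivation-count
check is the tool offered to test it empirically.  Exact-mode reweighting
of trained grammars is impractical (denominator blow-up) and exists for
small grammars only.
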