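# Methods

## Data model

The knowledge graph is a typed property multigraph with three node kinds —
compounds (identity: full standard InChIKey), protein targets (identity:
UniProt accession) and patterns (identity: canonical scaffold SMILES) — and
four directed edge kinds: compound→target bioactivity (`TESTED_ON`),
target→target causal interaction (`REGULATES`), pattern→compound membership
(`PATTERN_OF`, "C2P") and target→pattern potency (`POTENT_PATTERN_OF`,
"T2P"). Every node and edge carries a UUID: version-4 random identifiers in
production, or a seeded deterministic sequence for reproducible builds.

Compound identity is deliberately the *full* InChIKey while the 14-character
non-stereo block (NS-InChIKey) is a non-unique lookup attribute: resolving a
query by NS key may legitimately return several stereoisomer nodes, which is
the desired behaviour when the stereochemistry of a screening hit is
uncertain. Pattern identity, by contrast, is computed on structures stripped
of stereo descriptors, so stereoisomers share one scaffold node.

## Bioactivity aggregation

Raw activity rows are reduced to unique (compound, target, activity-type)
triples. Each measured concentration is first converted to −log₁₀(molar)
("p-value" in the potency sense: 10 µM ↔ 5, 0.1 µM ↔ 7); the aggregate is
the **median on that log scale** (for an even count, the mean of the two
central p-values). Aggregating on the log scale rather than on raw
concentrations matches how the potency threshold `p` is applied downstream;
for odd counts the two choices coincide. Only IC50/AC50/EC50 rows are used;
Ki and other types are discarded. Rows with censored values (`>`, `<`, `~`)
are dropped and counted in the parse report — a censored measurement has no
defined place in a median. Restriction to one organism is the caller's
concern (an optional taxon-column filter is provided); the engine itself is
organism-agnostic.

One `TESTED_ON` edge is stored per (compound, target) pair, holding the
per-type map of medians and their maximum (`best_p`); this keeps the
p-filter a single attribute comparison. Duplicate causal-interaction rows
collapse at assembly to one edge per (source, target, mechanism), keeping
the maximum confidence — parallel edges with different mechanisms are
preserved.

## Scaffolds and the overlap ratio

Patterns are classical Bemis–Murcko frameworks: ring systems plus the
linkers connecting them, exocyclic side chains removed, elements and bond
orders retained (no generic-skeleton reduction). Before extraction the
largest covalent fragment is kept (salts/mixtures) and stereochemistry is
stripped. Acyclic molecules have no framework; they remain graph nodes but
contribute no pattern edges. The pattern/compound **overlap ratio** is the
heavy-atom count of the pattern divided by that of the compound (counted on
the same largest fragment the scaffold came from), so it always lies in
(0, 1] and equals 1 exactly when a compound is its own framework. No atom
mapping is attempted — the ratio is a size proxy for how much of the
compound the pattern explains, and it is the only ranking score used for
predictions; no probability calibration is attempted.

Patterns attached to fewer than 5 or at least 100 compounds are pruned
(half-open interval [5, 100)): very rare scaffolds carry no generalizable
signal and very common ones are uninformative. The filter is idempotent and
never leaves dangling edges.

## Potency rules

Per target, the value multiset is every aggregated (compound, type) p-value
across its bioactivity edges, lumped regardless of type. With n values:

* n ≤ 5 (sparse rule): cutoff fixed at 7.0 (0.1 µM). A handful of values
  makes a quantile meaningless.
* n > 5 (quantile rule): the cutoff is the ⌈0.2·n⌉-th largest value; a
  compound is potent when **any** of its per-type values reaches the
  cutoff. Values tying the cutoff are all included, so under ties the
  potent set may exceed 20% but never falls short; the rule is exact
  otherwise (for distinct values, |potent|/n ∈ [0.2, 0.2 + 1/n)). The rule
  is rank-based, hence invariant under any monotone shift of the values.

Every pattern carried by a potent compound becomes a potent pattern (T2P
edge) of that target — set semantics, one edge per (target, pattern) pair.
T2P derivation requires the labeling stage to have run and replaces any
existing T2P edges, making it idempotent. Targets are treated independently;
no cross-target coupling of cutoffs is attempted.

## Predictions

A prediction is a (compound, target, pattern) triple where the pattern is
simultaneously T2P of the target and C2P of the compound. Both query
directions enumerate the same triple set (a symmetry the tests check).
Pairs with an existing measured bioactivity are excluded by default and
flagged when included. One row is emitted per shared pattern rather than
aggregating multiple shared patterns into one score — the per-pattern
provenance is the useful part of the hypothesis. Output order is
deterministic: overlap descending, then InChIKey, then pattern key.

## Path search

The search operates on the protein layer only: REGULATES edges with
confidence ≥ c, traversed in their stated direction. Start compounds seed
the targets they were tested on with best_p ≥ p; named proteins seed
themselves. For each (seed, end) pair the directed shortest-path length L
is computed and, if L ≤ k, **all** paths of length exactly L are collected
(networkx all-shortest-paths under the hood); a pair with seed == end
contributes a single-node path. Pairs are independent — paths of different
lengths may coexist in the merged subnetwork. Seed compounds and their
qualifying bioactivity edges are attached to the merged result; the
compound hop is *not* counted toward k, since k limits propagation between
proteins while p independently governs the bioactivity hop. Leaving end
nodes undefined is exploration: use start-node resolution plus type-filtered
neighbor expansion/hiding instead of a path search.

`max_connecting_confidence` finds the largest c still yielding a non-empty
subnetwork by bisecting the sorted set of edge-confidence values —
connectivity is monotone non-increasing in c, non-increasing in p and
non-decreasing in k (a property the tests verify against exhaustive
depth-limited path enumeration on random graphs).

## Synthetic fixtures

The generator emulates the two input tables at toy scale with a planted
truth. Compounds are decorations of twelve hard-coded valid ring templates
(benzene, pyridine, naphthalene, indole, biphenyl, ...): 1–4 acyclic
substituents attached to carbons with free valence, so each compound's
extracted scaffold provably equals its template and overlap ratios vary in
(0, 1). Defaults — chosen as a realistic miniature of a screening campaign:
6 scaffolds × 10 compounds, 6 targets, one planted potent scaffold per
target, carrier potencies Normal(8.0, 0.3) vs background Normal(5.0, 0.3)
on the p-scale (a 3-log separation, comfortably above the 2-log level the
recovery tests require), 3 replicate rows per triple with ±0.1 log jitter,
concentrations emitted in nM, a 10% share of planned triples emitted as Ki
(exercising type filtering), directed Erdős–Rényi regulatory edges
(probability 0.15) with Beta(2, 2) confidences, and 2 carriers per planted
pair held out untested. Per target the tested set is balanced so surviving
carriers are exactly the potent fraction of it (non-carriers are trimmed
after the Ki draw); unplanted targets receive ≤ 5 weak values so the sparse
rule labels nothing. Carriers lacking any dose–response row on a target
(held out, or drawn as Ki) are exactly the compounds prediction must
return.

What the fixtures do **not** emulate: real chemical diversity (a dozen
scaffolds, simple substituents), assay noise structure beyond symmetric
log-jitter, censored values, inter-target correlation of potencies, or
database-scale volumes. Passing the recovery tests therefore demonstrates
the correctness of the aggregation → assembly → potency → prediction chain
under clean separation, not predictive performance on real screening data.

## Numerical and design choices

* Medians of even-sized groups: arithmetic mean of the central pair.
* Ties at the potency cutoff: all included (see above); ties between
  equal-overlap predictions break deterministically by identity keys.
* Degenerate inputs: empty value sets raise; empty graphs serialize to
  valid empty documents; acyclic compounds are nodes without patterns.
* Unparseable structures raise a structure error carrying the offending
  SMILES rather than being silently dropped — input tables are expected to
  be pre-curated, and the parser reports (not raises) on missing fields.
* Test problem sizes: oracle-equivalence runs use 200 random graphs of up
  to 30 proteins and 60 edges against exhaustive depth-limited enumeration;
  planted-truth recovery runs 20 fixture seeds end to end; round-trip
  checks use 100 random graphs. These sizes exercise every code path while
  keeping the default suite fast.

## Known limitations

* The quantile rule's tie handling ("include all at the cutoff") is a
  modeling choice; an implementation ranking ties arbitrarily would label
  fewer compounds potent on targets with many identical measurements.
* Quality filtering of assays (confidence scores, relation flags) beyond
  type/unit/censoring validity is out of scope; inputs are taken as
  curated.
* The bulk CSV export targets batch import tooling and is not itself
  re-importable by this package (GraphML and node-link JSON are the
  lossless round-trip formats).
* Predictions are hypotheses ranked by a size ratio, not calibrated
  probabilities.
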