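# pharmgraph

A network-pharmacology knowledge-graph toolkit for drug-discovery
investigators. It integrates two layers of evidence — experimentally
measured compound→protein bioactivities (DTIs) and directed, curated
protein→protein causal interactions with confidence scores — into a single
typed property graph, and supports two analyses over it:

1. **Scaffold-based bioactivity prediction.** Bemis–Murcko scaffolds (ring
   systems plus their connecting linkers, side chains removed) are extracted
   from every compound. Per target, compounds in the top 20% of aggregated
   bioactivities (ranked in decreasing order of potency) are labeled
   *potent*; for sparsely tested targets (≤ 5 aggregated values) a fixed
   cutoff of 7 on the −log₁₀(M) scale (0.1 µM) is used instead. Every
   scaffold carried by a potent compound becomes a *potent pattern* of that
   target, and any untested compound sharing a potent pattern is predicted
   as a candidate modulator — ranked by the pattern/compound heavy-atom
   overlap ratio.
2. **Network-perturbation analysis.** Between user-chosen start nodes
   (compounds given by NS-InChIKey, and/or proteins by UniProt accession)
   and end proteins, the toolkit returns *all* directed shortest paths
   through the causal-interaction layer, subject to three parameters:
   `k` — maximum path length in regulatory edges (default 5), `p` — minimum
   DTI potency in −log₁₀(M) units for a compound to seed a target (default
   5, i.e. 10 µM), and `c` — minimum interaction confidence (default 0,
   no filtering). Merged paths form a subnetwork for mechanism-of-action
   hypothesis generation.

Bioactivities are aggregated per unique (compound, target, activity-type)
triple as the median of the measured values on the −log₁₀ molar scale;
only dose–response potency types (IC50/AC50/EC50) are used. Compounds are
identified by full standard InChIKey; the 14-character non-stereo block is
kept as a lookup attribute, so stereoisomers are distinct nodes sharing one
NS key and one scaffold. Scaffolds attached to fewer than 5 or at least 100
compounds are pruned as too specific or too general.

## Worked example

Generate a seeded synthetic study (decorated-scaffold compound library,
replicated nM activities, a confidence-weighted regulatory network, and a
ground-truth JSON), build the graph, and predict:

```
$ pharmgraph fixtures --out demo --seed 7
$ pharmgraph build --dti demo/dti.tsv --ppi demo/ppi.tsv \
      --out demo/graph.json --seed 7
{
 "compounds": 60,
 "dti_edges": 202,
 ...
 "patterns_post_filter": 6,
 "potent_pattern_edges": 6,
 "targets": 6,
 "targets_with_potent_pattern": 6
}
$ pharmgraph predict --graph demo/graph.json --target P10000
inchikey                     uniprot  pattern    overlap   already_tested
ODLMAHJVESYWTB-UHFFFAOYSA-N  P10000   c1ccccc1   0.666667  false
KPIPZJIYUBSVEK-UHFFFAOYSA-N  P10000   c1ccccc1   0.400000  false
WVUCITRAKAIXCY-UHFFFAOYSA-N  P10000   c1ccccc1   0.400000  false
```

The build report counts the assembled graph: 60 compounds over 6 scaffold
patterns, 202 aggregated compound–target edges, and one potent-pattern
(T2P) edge per planted (scaffold, target) pair. The three predicted
compounds are exactly the benzene-scaffold carriers held out from testing
on target P10000 (per `demo/truth.json`), ordered by how much of each
compound the shared scaffold explains (6 of 9 heavy atoms for the first
candidate). `pharmgraph paths --graph demo/graph.json --start <NS-key> \
--end <accession> -k 5 -p 5 -c 0.01` extracts the shortest-path subnetwork
between any start and end nodes, and `pharmgraph expand` lists neighbors of
a node by type. Real inputs use the same commands: a ChEMBL-style activity
export (`--dti-preset chembl`) and a SIGNOR-style causal-interaction export
(`--ppi-preset signor`), or custom column maps via `--config`.

Graphs serialize to GraphML, node-link JSON (both lossless) and a
bulk-import CSV dialect (one file per node label and edge type, UUID and
identity keys included) for loading into a graph database.

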