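# netpharm

Network-pharmacology analysis of multi-herb formulas, built around the
classic deconstruction of Xiaoyao powder (XYP), a six-herb traditional
Chinese medicine prescription used against anovulatory infertility.  The
package is for computational biologists who want the full pipeline —
typed network construction, three-index hub selection and gene-set
over-representation — as tested, scriptable code instead of a chain of
web services, together with a synthetic-data generator that reproduces
the statistical structure of the original inputs (which were never
deposited).

## What it computes

**Typed networks.** From tab-separated relation tables (herb→compound,
compound→predicted target, disease-target list, String-style scored PPI
edges with the conventional strict `combined_score > 0.4` filter) the
package builds four undirected simple graphs whose nodes carry role
labels:

1. herb – compound – pharmacology – traditional effect;
2. the bipartite compound – target map;
3. herb – target – disease, with compounds contracted out (each herb
   joins the union of its compounds' targets) and disease targets
   attached through their PPI edges with compound targets;
4. the PPI neighbourhood of all compound and disease targets.

**Hub selection.** Every node is scored by degree, pair-normalized
Brandes betweenness, and component-scaled (Wasserman–Faust) closeness

```
C(v) = (n_v − 1)/(N − 1) · (n_v − 1)/Σ_u d(v, u),
```

and a node is a *main node* when all three indices are at or above the
network-wide arithmetic means.  The direct-interaction subnetwork of
the main nodes (induced subgraph, isolates removed) is exported for
module analysis.

**Over-representation.** For a query list of n genes from a universe of
N, a term annotating K genes with k hits scores

```
FE = (k/n)/(K/N),    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n),
```

with Benjamini–Hochberg q-values, an optional EASE (k−1) variant, and a
greedy Jaccard-redundancy collapse that partitions the list into
functional modules.

## Worked example

```
netpharm generate --seed 1 --out inputs/
cat > run.yaml <<CFG
out_dir: out
herb_compounds: inputs/herb_compounds.tsv
compound_targets: inputs/compound_targets.tsv
disease_targets: inputs/disease_targets.tsv
ppi_edges: inputs/ppi_edges.tsv
annotations: inputs/annotations.gmt
pharm_efficacy: inputs/pharm_efficacy.tsv
CFG
netpharm run --config run.yaml
```

The run prints its count summary (abridged):

```
"compound_target_nodes": 244,      "compound_target_edges": 1065,
"herb_target_disease_nodes": 245,
"herb_target_disease_roles": {"herb": 6, "compound_target": 231,
                              "infertility_target": 6, "shared_target": 2},
"ppi_nodes": 1499,                 "ppi_edges": 54879,
"ppi_main_nodes": 336,
```

Reading: the bipartite map links 11 active compounds to 233 predicted
targets (244 nodes); contracting compounds yields a 245-node
herb–target–disease view in which 2 of the 9 infertility targets are
themselves compound targets ("shared") and one disease target drops out
for lack of PPI support among the targets; the seed neighbourhood in the
confidence-filtered PPI spans 1499 proteins, of which 336 exceed the
mean degree (73.2), betweenness (6.7e-4) and closeness (0.499)
simultaneously and count as main nodes.  `out/` also contains every
network as SIF + GraphML, per-node topology tables, the main-node
subnetwork, two enrichment tables and a module partition, plus a
`manifest.json` with a content hash per artifact (identical config and
seed reproduce identical hashes).

## Layout

- `src/netpharm/model.py` — validated domain types (tables, scored
  interactions, typed networks, results);
- `src/netpharm/io.py` — TSV/SIF/GraphML/GMT readers and writers with
  byte-deterministic output;
- `src/netpharm/synthetic.py` — generators (skewed bipartite map,
  scale-free scored PPI, planted annotation terms) and the study-scale
  fixture bundle;
- `src/netpharm/networks.py` — the four network builders and the
  main-node subnetwork;
- `src/netpharm/topology.py` — centralities and the above-average rule;
- `src/netpharm/enrichment.py` — fold enrichment, hypergeometric test,
  BH correction, module partitioning;
- `src/netpharm/pipeline.py`, `src/netpharm/cli.py` — the orchestrated
  run and the `netpharm` command.

See `docs/methods.md` for modelling assumptions and parameter choices.
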