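# Methods

## Problem setting

A multi-herb formula is treated as a perturbation of a molecular
network rather than a single-target drug.  The analysis starts from
already-resolved relation tables — herb→compound membership, predicted
compound targets (pharmacophore mapping output), a therapeutic-target
list for the disease indication, a scored protein–protein interaction
(PPI) catalogue, and GO-style annotation sets — and derives typed
networks, hub nodes, and over-represented biological processes.  The
package does not query any database: where the original inputs came
from web services, a generator produces tables with the same
cardinalities and statistical structure.

## Network construction

All networks are undirected simple graphs with one role label per node
(herb, compound, compound_target, infertility_target, shared_target,
other_protein, pharmacology, effect).  Role assignment over targets is
a partition: a protein in both the compound-target set and the disease
list is a `shared_target`, never counted twice.

* **Pharmacology–efficacy view.** Mirrors the curated table exactly;
  compounds lacking reported pharmacology keep only their herb edges.
* **Compound–target view.** Bipartite; node count is |compounds| +
  |targets| and edge count the number of distinct pairs, by
  construction.
* **Herb–target–disease view.** Compounds are contracted out: a herb
  joins the union of its compounds' targets.  This is the only reading
  consistent with a herb/target-only census.  Disease targets that are
  not compound targets are attached solely through their PPI edges with
  compound/shared targets (the "target relation"); a pure disease
  target with no such interaction has no incident edge in this view and
  is therefore dropped, with a log line naming it.  This one rule also
  explains why the disease side can show fewer entries here than in the
  PPI view, which keeps every seed.
* **PPI view.** Node set = seeds (compound ∪ disease targets) plus
  every direct PPI partner of a seed; edge set = all filtered
  interactions with both endpoints in that node set, so partner–partner
  edges are retained.  Interactions are expected to be pre-filtered by
  the strict `combined_score > 0.4` rule (strictly greater; an edge at
  exactly 0.4 is excluded).  Duplicate pairs collapse to the maximum
  score; self-interactions are dropped and counted.
* **Main-node subnetwork.** Induced subgraph on the selected hub set
  followed by isolate removal ("direct interaction" is read as: a main
  node must interact with another main node to appear).  An alternative
  reading — restricting to annotation-term members first — can be
  composed manually by intersecting the main set with term members
  before induction; isolate removal is the default path.

## Topological indices and hub rule

Degree, betweenness and closeness are computed on the unweighted
graph.  Betweenness is Brandes' algorithm with fractional credit over
equally short paths, endpoints excluded, normalized by (N−1)(N−2)/2 so
values lie in [0, 1]; on a ~1500-node network plausible thresholds are
then of order 1e-3, matching how network-analysis tools of the study's
era reported them.  Closeness uses the component-scaled
Wasserman–Faust form, which degrades gracefully on disconnected PPI
networks and is 0 for isolates.  Both are delegated to networkx and
verified in the test suite against an independent exhaustive
shortest-path enumeration oracle on all small graphs.

A *main node* has all three indices at or above the arithmetic means
taken over **all** nodes of the analyzed network, isolates included.
The comparison is inclusive (≥) with a 1e-9 relative float slack, so a
perfectly regular graph selects every node.  Selection is monotone:
raising a node's indices can never deselect it.

## Over-representation analysis

Fold enrichment is the exact ratio (k·N)/(n·K).  The p-value is the
plain hypergeometric upper tail P(X ≥ k); the conservative EASE variant
(tail at k−1) is available behind a flag but is not the default, since
the plain tail is the statistic actually defined by the sampling model.
Benjamini–Hochberg q-values are reported alongside, but significance
filtering uses raw p (default cut 0.05) to mirror how such results are
conventionally reported; q is informational.  The universe is
self-contained: genes appearing in the annotation collection
intersected with the analyzed network's symbol space.  Annotation
members outside the universe are dropped with a logged count.

Functional modules: significant terms are scanned in ascending-p order;
a term whose member overlap with an earlier retained term exceeds
Jaccard 0.5 is absorbed (near-synonymous GO terms collapse onto the
first representative); each gene goes to the most significant retained
term covering it, the rest to "unassigned".

Because the universe is the network itself (~1500 genes) rather than a
genome-wide background, fold enrichments for large query lists are
bounded by N/n and cannot reach the double-digit values a genome-wide
background produces; planted-term folds are therefore verified against
the list they were planted for.

## Synthetic data: what it emulates, and what not

* **Bipartite compound→target map.** A configurable number of
  "promiscuous" targets is hit by every compound (the centre of the
  observed centre/periphery pattern; these reuse the published symbols
  AR, BACE1, CA2, GSTA1 for readability); every other target draws its
  compound count from a geometric law (p = 0.15) truncated to
  [1, n_compounds], giving a right-skewed mean of ≈4.5 compounds per
  target so that 11 compounds × 233 targets lands at the observed
  ~1075-edge scale.  Only the counts and the promiscuity pattern are
  emulated; no chemistry enters.
* **PPI layer.** Barabási–Albert preferential attachment over anchors
  (targets) plus 1259 novel proteins, with anchors shuffled uniformly
  among attachment positions; i.i.d. uniform(0.15, 1.0) confidence
  scores make the >0.4 filter's expected loss analytic:
  0.25/0.85 ≈ 29.4%.  The default mean degree 108 (BA m = 54) is chosen
  so the *filtered* network reproduces the published ~55k-edge scale on
  1499 nodes.  Real PPI confidence scores are neither uniform nor
  independent of degree; no evidence channels are modelled.
* **Fixture engineering.** Three deterministic repairs make the
  published censuses exact for every seed: one designated disease
  target keeps no above-cutoff edge to any target (so the
  herb–target–disease view shows 6 + 2 disease entries while the PPI
  view keeps all 7 + 2); every other pure disease target keeps at least
  one supporting edge; every novel protein keeps at least one
  above-cutoff edge to a seed so the seed neighbourhood spans the full
  1499-protein pool.
* **Annotations.** One term (or several, on disjoint hub-gene chunks)
  is planted so its realized fold enrichment against the hub list
  matches the requested value — the term size is re-fitted by a few
  genes around the integer overlap so the fold is exact to one-gene
  granularity; remaining terms are uniform draws from the universe.
  The study-scale bundle plants four disjoint modules named after
  reproductive-endocrine GO processes on the 40 best-connected
  compound targets, at fold 7.1 (the headline reported value).
* **Planted-hub benchmark.** A separate generator plants an
  unambiguous hub set (8 hubs in a 300-node graph, clique among hubs,
  80% attachment to all nodes, background mean degree 3) and returns
  the ground truth, for measuring hub-recovery of the above-average
  rule.
* **Engineered subnetwork fixture.** A 235-node main set inside a
  larger network in which exactly 112 main nodes (31 compound targets,
  1 infertility target, 1 shared target, 79 other proteins) interact
  with another main node; the other 123 touch only non-main satellites.

Passing tests on these generators demonstrate that the *procedures*
(construction rules, selection rule, statistics) behave as specified
under controlled conditions; they do not validate the biological claims
of any particular formula–disease pair, and real prediction noise
(pharmacophore false positives, PPI ascertainment bias, annotation
incompleteness) is not modelled.

## Numerical and format conventions

* Gene symbols are uppercased on ingestion; unordered PPI pairs are
  stored lexicographically.
* All writers sort output canonically; the run manifest hashes each
  artifact (SHA-256), and identical config + seed reproduce identical
  hashes.
* Node-attribute tables print reals with fixed 6-decimal
  round-half-even formatting (decimal, not binary, rounding).
* All randomness flows from a single integer seed through named
  per-generator streams, so the bundle is byte-reproducible.
* Enrichment ties are broken by descending fold enrichment then term
  id; topology tables sort by descending degree then node id.

## Problem sizes used in the checks

The structural identities run at the study scale (1499-node PPI layer,
~55k filtered edges; full pipeline ≈ 30 s).  Statistical recovery
suites run at reduced scale chosen for tight analytics: oracle
equality on all graphs of ≤ 8 nodes; hypergeometric agreement for every
universe of ≤ 25 genes plus literal draw enumeration at N = 20;
planted-term recovery over 100 seeds on a 500-gene universe; hub
recovery over 50 seeds on 300-node graphs; filter-loss calibration over
20 seeds of ~4000-edge graphs.

## Known limitations

* The contraction rule for the herb–target–disease view and the
  isolate-removal reading of the hub subnetwork are reconstructions of
  under-specified figure semantics; both are the only readings we found
  consistent with the published censuses, and both are stated
  explicitly above.
* The self-contained enrichment universe understates fold enrichment
  relative to a genome-wide background (see above).
* Means for hub selection are taken over all nodes; no pre-exclusion
  variant is offered because no evidence distinguishes them.
* No weighted or directed centralities; edge scores are used only for
  filtering.
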