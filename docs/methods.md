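# Methods

## The model

The pipeline treats a multi-component intervention as a coverage problem on
a merged interaction graph. Three layers are assembled into one undirected
simple graph, the C-T-P network: a disease-gene layer (PPI subgraph induced
on genes whose database relevance score is strictly above a threshold,
default 5, isolated nodes removed), a bipartite component–target layer, and
all PPI edges among the included protein nodes. Node roles (component /
target / disease gene / both) and the relevance-score weights are carried as
attributes; the scoring formula itself sees only unweighted topology.

Node importance is the product of two normalized shortest-path quantities:

* closeness factor `(n−1) / Σ_k d(i,k)` — "leadership", how cheaply node *i*
  reaches everyone else;
* bridging factor `[Σ_{j<k, j≠i≠k} t_jk(i)/t_jk] / [n(n−1)/2]` — the average
  share of shortest paths between *other* pairs that pass through *i*
  (betweenness normalized by the number of unordered pairs, so it lies in
  [0, 1]).

Nodes scoring strictly above the arithmetic mean form the critical response
network (the induced subgraph on those nodes, in a single pass — scores are
not recomputed after reduction); its non-component members are the effective
proteins. Component selection is greedy maximum coverage over the
effective-protein universe; the core active component group is the shortest
selection prefix at the requested coverage (default 100%). Validation uses
one-sided upper-tail hypergeometric enrichment with the raw p < 0.05 gate;
intervention terms are the intersection of target-enriched and
disease-enriched terms, and competing node-scoring models are compared by
the fraction of intervention terms their effective proteins recover.

Assumptions worth stating explicitly: the graph is undirected, unweighted
and loop-free (self-loops are discarded at ingest, along with nodes that
appear only in self-loops); gene identity is exact symbol match after
trim+uppercase normalization, with no alias resolution; relevance scores
gate admission to the disease layer but never enter the importance formula;
and the selection optimizes coverage only — component costs (dose, toxicity,
synergy) are out of scope.

## Design choices where the design was open

* **Which PPI edges enter the C-T-P network.** All PPI edges between any two
  included protein nodes (targets or disease genes), not just edges touching
  disease genes — the merged network is meant to expose bridging structure
  among targets too. The builder takes the full PPI as an explicit argument,
  so a stricter rule can be applied upstream by pre-filtering that input.
* **Selection semantics.** The selection is implemented as weighted greedy
  maximum coverage (pick the argmax marginal gain, stop at zero gain). With
  unit component costs this coincides with the knapsack-flavored dynamic
  programming formulation; the greedy curve is exactly the cumulative
  contribution narrative the coverage table reports, and an exhaustive
  subset-search oracle (gated to ≤ 20 components) verifies optimality
  behavior in tests.
* **Tie-breaks.** Equal marginal gains resolve toward the larger total
  effective-target count, then the lexicographically smaller component id;
  selection output is therefore a deterministic function of its inputs.
* **Enrichment gate.** Raw p < 0.05, with Benjamini–Hochberg adjusted values
  available as an extra column but not gating by default. The background
  universe defaults to the union of the loaded gene sets unless supplied.
* **Include-list semantics.** Literature-documented high-concentration
  components join the active set by union, bypassing the ADME property
  filter entirely (they are not given relaxed thresholds).

## Numerical choices

* Shortest-path quantities come from a level-synchronous Brandes
  accumulation where a batch of BFS sources is advanced simultaneously and
  each level is one sparse-matrix × dense-matrix product (`_brandes.py`).
  This keeps the O(nm) total work in BLAS-speed array operations: the
  ~1500-node / ~30000-edge scale run completes in under two seconds, so no
  sampling approximation is needed. Tests verify agreement with an explicit
  all-shortest-paths enumeration (≤ 1e−12) on every connected graph with up
  to 7 nodes and on seeded random graphs, and cross-check the two factors
  against networkx's closeness and betweenness.
* **Above-mean rule and round-off.** The CRN rule is a strict inequality. On
  graphs whose scores are all equal in exact arithmetic (any
  vertex-transitive graph), floating-point accumulation leaves the values a
  few ulps apart, so the comparison uses a relative guard of 1e−9 — far
  below any meaningful score difference — and such graphs yield an empty
  CRN, the documented behavior.
* **Disconnected input.** The scorer refuses disconnected graphs by default
  (the printed formula assumes finite distances). In `componentwise` mode,
  unreachable pairs contribute zero to the bridging numerator and are
  excluded from the closeness denominator, while both normalizations keep
  the global *n*; this is the mode the full-scale synthetic run uses, since
  a thresholded disease layer can leave small satellite components.
* **Degenerate inputs.** Fewer than 3 non-isolated nodes is an error (the
  bridging factor is undefined); an empty CRN, an empty C-T association
  table after screening, and a coverage target that is unreachable are all
  explicit, non-exceptional results.
* Hypergeometric tails are `scipy.stats.hypergeom.sf`; tests compare against
  direct binomial-coefficient summation for every margin combination with
  universe ≤ 30.

## What the synthetic data emulates — and what it does not

`SyntheticConfig` defaults define the study conditions used throughout the
tests: 120 proteins, preferential-attachment PPI (3 edges per node for the
generic generator), 60 candidate disease genes with log-normal relevance
scores (μ=2.0, σ=0.6 on the log scale, so roughly a quarter fall below the
threshold of 5), 24 components with a 60% ADME pass rate (property draws
straddle every cutoff), 3–10 targets per component with half drawn from
disease genes, and 30 annotation terms of 6–15 genes.

The planted fixture makes the ground truth provable rather than merely
probable. Twelve bridge proteins (core size 4 × tile size 3) sit on a cycle,
each the sole gateway to its own leaves, so their bridging factor is large;
decoy components anchor on one bridge and otherwise target only leaves of
that same bridge, which keeps those leaves off all inter-node shortest paths
(the anchor route is never longer); and a dense clique module wired entirely
through one bridge has high degree and clustering but exactly zero
betweenness. Measured across seeds, bridge scores exceed the network mean
more than two-fold while every other protein stays below 3% of it, so the
effective-protein set equals the designed bridge set and greedy selection
returns exactly the planted core — which is also why the degree and
clustering baselines, trapped by the clique, recover none of the
intervention terms the composite score recovers. The annotation universe
includes extra background-only symbols, as real collections cover more genes
than any one study.

What the generators do **not** emulate: real degree-correlation and module
structure of curated PPI databases, literature-biased relevance scores,
correlated ADME properties within chemical series, or hierarchical GO
topology (terms are flat sets). Passing tests therefore demonstrate
correctness of the algorithms and recoverability under controlled
conditions, not performance on any particular curated database snapshot.

## Problem sizes

Unit and property tests run on graphs of 3–40 nodes; oracle equivalence
covers all 853 connected ≤ 7-node isomorphism classes plus 200 seeded random
graphs; selection optimality uses 500 seeded instances of ≤ 12 components
over ≤ 20 proteins against exhaustive search; recovery uses 100 fixture
seeds; and the scale run assembles a ~1500-node, ~30000-edge C-T-P network —
the size regime of a real single-disease, single-formula study. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* No directed or weighted shortest-path variant; relevance weights and edge
  provenance are reporting attributes only.
* Exact selection is exponential and deliberately gated to 20 components;
  beyond that only the greedy curve (with its (1−1/e) guarantee) is
  available.
* Gene-set enrichment treats annotations as flat sets; parent/child term
  redundancy is not collapsed.
* Symbol matching is exact after normalization; identifier mapping across
  nomenclature revisions must happen upstream.
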