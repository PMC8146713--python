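# Methods

`dupnet` implements the network-medicine workflow used to connect rare
chromosomal duplications to a shared phenotype (here: intellectual
disability, ID): map each duplicated region to its protein-coding genes,
embed those genes in a confidence-filtered protein–protein interaction (PPI)
network, profile the topology of the expanded neighborhood, prioritize
candidate genes by heat diffusion from a curated disease-gene list, and
characterize the result with functional-module detection, gene-set
over-representation, and gene–disease / tissue association networks.

## The interactome and the eDSi

The substrate is an undirected, gene-symbol-keyed graph with a per-edge
confidence score in [0, 1] (the HIPPIE export dialect). Construction:

1. **clean** — drop self-loops, collapse duplicate unordered pairs keeping
   the maximum score (best evidence wins). Idempotent.
2. **filter** — keep edges with score strictly above a threshold (default
   0.4). Strict inequality is deliberate and matters at the boundary: a
   score of exactly 0.4 is removed. Nodes isolated *by* the filtering are
   dropped; pre-existing isolates are kept.
3. **largest connected component (LCC)** — all later statistics are
   computed on the LCC. Ties (same node count) are broken by edge count,
   then lexicographically, so the choice is deterministic.

Seed genes are the protein-coding genes inside the duplicated regions.
Region strings (`chr8:126,397,316-143,577,971` style, 1-based inclusive,
hyphen or en-dash, thousands separators allowed) are intersected with a
BED-convention annotation (0-based half-open; both are converted to 1-based
inclusive before comparison). The default overlap rule is *any overlap*
(≥ 1 shared base), matching genome-browser region queries;
*full containment* is available. A gene with several annotation rows counts
once, by symbol.

The **eDSi** (expanded duplication-syndromes interactome) is the seed set
plus all first neighbors. Two expansion modes:

* **incident** (default): keep exactly the LCC edges touching a seed. Every
  seed then provably keeps its full-interactome degree, and the subnetwork
  is star-like and sparse — consistent with the density reported for this
  kind of expansion.
* **induced**: keep every LCC edge among the retained nodes.

## Topology

Centralities are exact (no sampling), unweighted, per connected component:
degree; betweenness normalized by (n−1)(n−2)/2 with n the component size;
closeness = (reachable count)/(sum of distances), so closeness equals
1/(average shortest path length) on a connected graph; and the per-node mean
shortest-path length (undefined for singletons, excluded from means).
Normalized betweenness is the only convention consistent with
interactome-scale background means of order 1e-4.

Background means are computed over the full interactome LCC; per-node
profiles over the eDSi. Flags use strict inequalities and ties classify
negative: *hub* = degree > 100 (the conventional multifunctionality cutoff),
*bottleneck* = betweenness > background mean, plus high-closeness and
short-path flags. Summary percentages are reported over the seed genes,
rounded to the nearest integer. Betweenness and shortest-path matrices come
from igraph's C routines; their correctness is pinned against a brute-force
oracle that enumerates every shortest path explicitly (exhaustively on all
labelled connected graphs with ≤ 5 nodes, plus 500 seeded random graphs of
4–20 nodes, tolerance 1e-12 — sizes chosen to keep the oracle's explicit
path enumeration exact and fast).

## Heat-diffusion prioritization

Initial heat h0 places 1.0 on each query (disease-list) gene present in the
eDSi, 0 elsewhere. Propagated heat is h(t) = exp(−t·L)·h0 with L the
unnormalized Laplacian of the unweighted eDSi — the published behavior of
the Cytoscape Diffusion app the workflow names — computed with
`scipy.sparse.linalg.expm_multiply` and verified to 1e-8 against a
scaling-and-squaring truncated-Taylor oracle with an explicit remainder
bound. Column sums of L are zero, so total heat is conserved (checked to
1e-10). Defaults: t = 0.1; a confidence-weighted Laplacian is optional.

Nodes are ranked by heat descending, ties broken lexicographically; the top
`max_rank` (default 302) nodes form the selected set, query genes included
by default (an exclude option exists because either reading of a rank
cutoff is defensible). The prioritized candidates are the seed genes inside
that window, annotated with region and rank.

## Modules and over-representation

Module detection is the shared-k-nearest-neighbor (SKNN) + Louvain scheme
used by tissue functional-network servers, re-implemented generically: each
node lists its k (default 10; the upstream tool does not publish k)
highest-weight neighbors, ties lexicographic; nodes sharing a list member
or appearing in each other's lists are linked, weighted by shared count;
Louvain (seeded, deterministic for a fixed seed) maximizes modularity on
that graph.

Over-representation is the one-sided Fisher exact test — the
hypergeometric upper tail P(X ≥ k | N, K, n) — with Benjamini–Hochberg
step-up correction. The BH family for a module run is every (module, term)
pair of that run; the background universe defaults to the analyzed
network's nodes and is recorded in output metadata, because both choices
materially change p. Module results are thresholded on q < 0.05, the
pathway-style enrichment of the prioritized gene list on raw p < 0.05,
mirroring how the two analyses are conventionally reported.

## Association networks

The gene–disease network restricts a scored association table (max score
kept on duplicate pairs) to the genes of interest and reports per-disease
gene counts and per-gene disease counts. The tissue subnetwork keeps the
query genes, then greedily adds up to `max_added` (default 15) non-query
genes in descending order of their strongest single connection to the
current node set (maximum, not sum — deterministic with lexicographic
ties; a sum variant would be a one-line change), finally retaining edges
with confidence strictly > `min_confidence` (default 0.10). "Maximum number
of genes" is interpreted as the cap on *added* genes, matching the named
web tool's semantics.

## Synthetic study conditions

The generator emulates all six inputs with planted ground truth; the
dataset is a pure function of (config, seed) and every emitted file parses
back with zero skipped rows. Defaults (the package's study conditions,
a roughly eight-fold scale-down of the real analysis):

| parameter | default | why |
|---|---|---|
| interactome nodes / attachment | 2000 / 8 | preferential-attachment graph; mean degree ≈ 16 halfway to the real LCC's 32, and dense enough that the eDSi exceeds the 302-rank window so the published cutoff binds |
| edge scores | Uniform(0, 1) | ≈ 60% of edges survive the 0.4 screen (binomial-checked) |
| regions × genes | 3 × 15 | about half the 89 seed proteins of the motivating analysis |
| disease module size / causal seeds | 25 / 8 | connected non-seed gene set; its members are the disease-gene query list |
| wiring probability causal / background | 0.6 / 0.02 | causal seeds gain ≈ 9 disease-module neighbors, non-causal ≈ 0.3; setting both equal gives the null configuration |
| GMT library | 40 terms × 20 genes, 100:1 planted odds | the planted term draws from the disease module at 100:1 odds — strongly enriched against 39 uniform null terms |
| diseases | 12 + planted | the planted disease covers all causal seeds plus each other seed w.p. 0.35, making it the most-associated disease by construction |

Each region also plants decoy protein-coding genes ending exactly one base
outside the region boundary and non-coding entries inside it; correct
mapping must exclude both. Coordinates live on one artificial chromosome
(`chrS`) to avoid assembly semantics.

What the generator does **not** emulate: realistic gene lengths or isoform
structure, literature-biased confidence distributions, degree-correlated
interaction evidence, or disease-ontology structure. Passing recovery tests
therefore show the machinery is correct and well-calibrated on scale-free
topology with planted signal — not that the biological conclusions of any
particular real dataset would be reproduced.

## Numerical and design choices

* All rank/tie situations break lexicographically by gene symbol; every
  stage is deterministic given (inputs, config, seed), and a full pipeline
  rerun is byte-identical on all tables and the manifest.
* Strict (`>`) thresholds everywhere a cutoff is stated; equality never
  passes a filter or sets a flag.
* Seed centralities are computed within the eDSi (where incident-mode
  degree equals full-interactome degree); background means on the full LCC.
  An option computes profiles on the full interactome instead; the choice
  is visible in the run manifest.
* The combined "closeness *and* path length above average" summary is not
  reproduced: high closeness implies *low* path length, so the four flags
  are reported separately instead.
* Degenerate inputs: empty graphs raise for profiling/diffusion; singleton
  modules are tested like any other; empty prioritized sets propagate as
  empty tables with warnings, not errors.
* Acceptance experiments (scripts/acceptance.py) use 500 random graphs for
  the centrality oracle, 100 graphs ≤ 200 nodes for the diffusion oracle,
  200 exact hypergeometric checks at N ≤ 30, 20 diffusion-recovery and 100
  enrichment-recovery replicates at the default conditions — sizes at which
  the brute-force oracles are exact and the whole script runs in about a
  minute.

## Known limitations

* No identifier mapping: gene identity is the symbol string throughout;
  symbol collisions between a gene and a disease label in one table are not
  namespaced.
* Betweenness is exact, so interactome-scale graphs (tens of thousands of
  nodes) take minutes, not seconds; no sampled approximation is provided.
* Only the unnormalized-Laplacian heat kernel is implemented; random walk
  with restart and degree-normalized kernels are extension points.
* Partial gene duplication, dosage effects and breakpoint biology are out
  of scope: region membership is binary.
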