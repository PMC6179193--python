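# Methods

## Model

`cassnet` clusters an undirected simple graph G = (V, E) by structural
similarity, in the SCAN lineage: two adjacent nodes are similar when their
closed neighborhoods overlap,

    sim(v, w) = |Nei(v) ∩ Nei(w)| / sqrt(|Nei(v)| · |Nei(w)|),
    Nei(v)    = {u : (v, u) ∈ E} ∪ {v}.

The denominator is the geometric mean of the two closed-neighborhood
sizes — the standard cosine normalisation, and the only common choice that
keeps the score in (0, 1] for an existing edge. For adjacent v, w the
intersection always contains both endpoints, so with t(v, w) triangles on
the edge and d(·) the degrees,

    sim(v, w) = (t(v, w) + 2) / sqrt((d(v) + 1)(d(w) + 1)),

which is the closed form the pipeline actually evaluates. Similarity is
defined only on edges; the algorithm never weights non-adjacent pairs.

The clustering itself is: prune edges with sim < ε; call a node core when
its pruned degree is ≥ m; delete edges joining two non-cores; the
connected components with ≥ 2 nodes of this refined graph are the
clusters, labelled by their minimum member id; everything else is
unassigned. All four steps are deterministic given the similarity table.

## The two-join triangle dataflow

Triangle counting is phrased as a keyed dataflow so that the same code
expresses a shared-nothing execution: records are (key, value) pairs,
records with equal keys always meet in the same hash partition, and all
per-partition work is pure. The partition count is a configuration knob
and provably cannot change any output (counts are aggregated across
partitions); tests assert this.

1. **First join** — edge records keyed by one endpoint are self-joined;
   each key with multiplicity c contributes c·(c−1) ordered candidate
   records (wedges: two edges, three nodes).
2. **Re-key + second join** — each wedge is re-keyed by its closing node
   pair (canonical min,max orientation) and joined against the edge set;
   surviving wedges are triangles. Each triangle found adds one to the
   per-edge count of all three of its sides.

Edge records are canonicalised to (min, max) before keying. This is a
correctness requirement, not a convenience: with raw file orientations a
cyclically oriented triangle (x→y, y→z, z→x) has no vertex with two
outgoing edges and would never be enumerated. With canonical records,
keying by the smaller endpoint finds every triangle exactly once at its
minimum vertex (and keying by the larger endpoint at its maximum vertex),
so both join directions are exact.

**Pipeline statistics** (candidates generated, candidates surviving the
Bloom filter, second-join records) are reported in ordered-record units —
the size a keyed self-join would materialise, i.e. Σ c·(c−1) — so one
unordered wedge counts twice. These statistics are the package's stand-in
for network shuffle volume; they never affect the similarity values, and
the invariants `after_bloom ≤ generated`, `found ≤ after_bloom`, and
`after_bloom = generated` when the filter is off all hold in these units.

### Bloom filter

Before re-keying, candidates whose closing edge cannot exist are dropped
by a Bloom filter built over the edge set. Sizing uses the textbook
optimum for n elements at false-positive rate p: m = ceil(−n ln p / ln²2)
bits and k = round((m/n) ln 2) hash functions (at the default p = 0.3:
m/n ≈ 2.51, k = 2). Probe positions come from double hashing of a 128-bit
BLAKE2b digest of the canonical edge encoding, with the second hash forced
odd so the stride covers all slots; the digest is salted with a
user-visible seed, making runs bit-reproducible. False negatives are
impossible by construction, so filtering can only remove candidates the
second join would reject anyway — the triangle counts are identical with
the filter on or off, at any false-positive rate.

### Shuffle selection

The self-join output grows with key skew. Approximating uniform key
multiplicities, joining with key set K costs about |E|²/|K| records, so
the cheaper side is the one with more distinct keys. The decision rule is
computed on the loaded file orientation — reverse keying is chosen iff the
file has fewer distinct source than destination vertices, ties go forward
— and is exactly the stated heuristic, with no correction for skew. For a
hub-out star this turns a quadratic candidate set into an empty one. The
chosen direction then selects which canonical endpoint (min or max) keys
the join; either choice is exact, so the heuristic affects only work, and
tests force both directions to confirm identical results.

## Quality metrics

All metrics are evaluated on the **original** graph (on the refined graph
every inter-cluster quantity is identically zero).

* **Normalized cut**: Ncut(A,B) = edge(A,B)/edge(A) + edge(A,B)/edge(B),
  with edge(A,B) the crossing-edge count. `edge(X)` is ambiguous in the
  one-line verbal definition it comes from; the default reads it as edges
  with ≥ 1 endpoint in X (incident convention), which bounds each pairwise
  term by 1 and matches the observed scale of published values; an
  internal-edges-only reading is available via `mode="internal"`.
* **Average N-cut** is the mean of Ncut over unordered cluster pairs with
  at least one crossing edge. Averaging over *all* pairs would drive the
  statistic to zero as cluster count grows and make values incomparable
  across networks; pairs without contact carry no separation information.
  With no connected pair the average is defined as 0. One caveat is
  documented deliberately: adding a crossing edge between clusters A and B
  never decreases the (A,B) pairwise term (its numerator grows by one
  while each denominator grows by at most one from a base at least as
  large), and the tests assert exactly that; the *average* over all pairs,
  however, can still decrease, because edge(A) also appears in the
  denominators of A's terms with third clusters. Only the pairwise
  monotonicity is claimed.
* **Modularity**: Newman's Q = Σ_c [L_c/|E| − (D_c/2|E|)²] with unassigned
  nodes as singleton communities, so degree mass is conserved and the
  trivial all-in-one partition scores exactly 0.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ε (`--epsilon`) | 0.7 | similarity threshold; edges with sim ≥ ε survive (ties kept — the prose rule prunes only *lower* values) |
| m (`--min-neighbors`) | 2 | pruned-degree threshold for core labeling, comparison ≥ m |
| false-positive rate (`--fp-rate`) | 0.3 | Bloom filter target FP probability |
| partitions (`--partitions`) | 1 | hash-partition count of the dataflow; affects nothing but grouping |
| seed (`--seed`) | 0 | Bloom hash salt (and generator seed in `synth`, where it is mandatory) |

Two documented ambiguities in the core rule are exposed as switches rather
than silently resolved. The source prose says a node is core with "more
adjacent nodes than m" (strict >), but the SCAN lineage and the worked
overview at m = 2 favor ≥; the default is ≥ with `--strict-core` for the
literal reading. Likewise SCAN's ε-neighborhood includes the node itself,
which would shift m by one; `count_self=True` in `label_cores` switches to
that convention. Neither switch changes any of the monotonicity
guarantees.

## Synthetic data

`erdos_renyi_graph(n, mean_degree, seed)` draws G(n, p) with
p = mean_degree/(n−1) — the generator is parameterised by target mean
degree because that is what the scaling experiments it supports control
(the canonical large-network workload is n in the thousands at mean degree
20). `planted_partition_graph(k, n_per, p_in, p_out, seed)` draws
independent within/between-block edges with p_in > p_out enforced and
returns ground-truth labels; recovery is scored by adjusted Rand index.
The reference recovery condition used in tests and the acceptance script —
4 blocks × 25 nodes, p_in = 0.6, p_out = 0.01, clustered at (ε = 0.3,
m = 2) — puts within-block edge similarities around 0.65 and cross-block
ones around 0.13, well on either side of the threshold.

Both generators draw row-by-row from `numpy.random.default_rng(seed)`, so
they are pure functions of (parameters, seed) without materialising the
full pair matrix.

What the synthetic graphs do **not** emulate: heavy-tailed degree
distributions, overlapping modules, weighted or directed interactions, and
the multi-million-edge scale of real interaction networks. Passing the
recovery and monotonicity suites therefore demonstrates correctness of the
pipeline's logic, not field performance on real biological data.

## Numerical and design choices

* Pipeline similarities agree with the direct set-intersection oracle
  bit-for-bit (both evaluate the same closed form on the same integers);
  the tested tolerance of 1e−12 is a safety margin, not an approximation.
* Ties at ε are kept; ties in the shuffle-selection rule go forward.
* All iteration orders are sorted, so cluster tables and caches are
  byte-identical across runs; the similarity cache stores floats with
  `repr` (shortest round-tripping decimal), so write→read is an exact
  identity.
* Component extraction is iterative minimum-label propagation to a fixed
  point (labels only decrease, hence guaranteed termination); a union-find
  and a networkx implementation serve as independent oracles in tests.
  Worst-case pass count is the graph diameter, acceptable at the scales
  this implementation targets.
* Degenerate inputs: self-loops are dropped on read with a report count
  (closed neighborhoods already include the node, so they carry no
  information); duplicate and reversed-duplicate lines merge to one edge;
  an empty graph yields an empty similarity table; a graph with no core
  nodes yields zero clusters with every node unassigned.
* Problem sizes in the test and acceptance suites (graphs up to ~500
  nodes, mean degree ≤ 12; 5,000-edge Bloom populations) were chosen so
  that exhaustive oracles — brute-force triple enumeration, per-edge set
  intersection — remain cheap enough to check every result exactly.

## Known limitations

* Single-process execution: the dataflow reproduces the *semantics* of a
  distributed keyed join (partition-pure operations, hash co-location) and
  reports intermediate-record counts as the proxy for shuffle volume, but
  no actual cluster deployment, serialization or wall-clock claims are
  made; stage timings in the CLI log are informational only.
* Directed and weighted input networks are out of scope; hub/outlier
  post-classification of unassigned nodes (as in SCAN) is deliberately not
  performed.
* The minimum-label-propagation component finder is quadratic in the worst
  case (long paths); swap in the union-find oracle if million-node refined
  graphs ever become a target.
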