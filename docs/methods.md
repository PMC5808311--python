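# Methods

## The model

`psnscan` treats a protein family's pairwise percent-identity matrix
*S* ∈ [0, 100]<sup>n×n</sup> as the sufficient statistic for its
phylogenetic structure.  Because directional alignment scores need not be
equal, *S* is first symmetrized conservatively,
*S<sub>ij</sub>* ← min(*S<sub>ij</sub>*, *S<sub>ji</sub>*): an edge should
exist only if both directions support it.  The single weighted network is
then replaced by a family of 101 unweighted graphs
*G*<sub>σ</sub>, σ = 0 … 100, with an edge (i, j), i ≠ j, iff
*S<sub>ij</sub>* ≥ σ.  Raising σ can only delete edges, so the family is a
nested filtration from the complete to the empty graph.

Each graph is summarized by its neighborhood matrix *M̂*, whose (i, j)
entry is the shortest-path length (BFS), 0 on the diagonal, and a sentinel
for unreachable pairs.  Consecutive graphs are compared with

&nbsp;&nbsp;δ(σ, σ+1) = Σ<sub>i&lt;j</sub> |*M̂*<sub>σ</sub>(i,j) − *M̂*<sub>σ+1</sub>(i,j)| / (n(n−1)/2),

a normalized L1 metric on upper-triangle entries (identity, symmetry and
the triangle inequality are property-tested).  The critical threshold
σ<sub>c</sub> is the argmax of the 100 δ values (smallest σ on ties);
remaining strict local maxima are reported as secondary peaks, since
hierarchical structure produces one transition per separation scale.

Communities of the critical network are found with the divisive
Newman–Girvan procedure: recompute edge betweenness, remove the single
largest-betweenness edge, record a split whenever a component disconnects,
repeat until no edges remain.  The removal history is a binary dendrogram
over the sequences — the network analogue of a phylogenetic tree, except
that branches are communities rather than clades.  The working partition is
the maximum-modularity configuration among all component configurations
visited during removal; a fixed community count can be requested instead
(`--k`).

Branch support is assigned by resampling the similarity matrix itself:
*S<sub>ij</sub>*/100 is taken as the success probability of a
Binomial(*T*, p) draw with *T* = the alignment length including gaps, and
*S′<sub>ij</sub>* = k·100/*T*.  This reproduces the variance profile that
character resampling would induce on similarity scores — variance
100²·p(1−p)/*T*, maximal near 50 % identity, zero at 0 and 100 — without
re-aligning anything.  Each replicate is thresholded at the *original*
σ<sub>c</sub> and run through the same community detection; the support of
a reference branch is the percentage of replicate dendrograms containing
that exact node set (exact-set clade-presence scoring).

Two classifications are compared with the congruence index: restrict both
to their *R* common organisms, match communities one-to-one by maximizing
total overlap (Hungarian assignment on the overlap-count matrix), and
report *G* = 100·*Q*/*R* where *Q* organisms fall in matched pairs.  *G* is
symmetric and equals 100 iff the partitions coincide on the common set.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| σ range | percent identity | 0–100, step 1 | the full filtration; integer steps match percent-identity resolution |
| sentinel for unreachable pairs | path length | n | exceeds any finite distance, so fragmentation dominates δ — exactly the transition the scan detects; configurable |
| bootstrap replicates | — | 1000 | standard bootstrap resolution (±~1.5 points Monte-Carlo error at p≈0.75) |
| bootstrap trials *T* | alignment columns | 4944 | the 42-sequence chitin synthase alignment length (incl. gaps); **must** be set to the dataset's own alignment length otherwise |
| NG tie-break | — | lexicographic smallest endpoint pair | determinism; ties are real (e.g. cycles) |
| partition rule | — | max modularity; ties → fewer communities, then earlier stage | automates the visual dendrogram/color-matrix reading deterministically |

## The synthetic generator

`psnscan.synth.planted_blocks` emulates the score-level structure the
pipeline assumes: within-family pairs ~ N(μ_in, sd), between-family pairs
~ N(μ_out, sd), clipped to [0, 100], symmetric, diagonal 100, deterministic
per seed.  An optional nested level (sub-blocks at μ_sub > μ_in) plants two
separation scales and hence two δ peaks.  Clipping (rather than truncated
resampling) is used because at realistic separations (several sd between
μ_out and μ_in) it is negligible.

`psnscan.chs.synthetic_study_matrix` is a labelled **synthetic** stand-in
for the non-redistributable published 42×42 chitin synthase matrix: the 42
published sequence ids with within-community mean 60 %, 40 % between the
sister communities C2–C3, 35 % between C1 and the rest, sd 4.  Those levels
were chosen so that, as in the published network, the three communities are
internally dense at the critical threshold and joined only by a few
boundary edges (C2–C3 more strongly than C1).  What the generator does
*not* emulate: heavy-tailed alignment-score noise, correlated errors from
shared alignment columns, within-family substructure, and the exact score
values of the real matrix — so passing tests demonstrate correctness of the
*method* and recoverability under realistic separations, not agreement with
the original data's absolute numbers (critical threshold, edge count,
index values), which are properties of the real scores alone.

## Numerical choices

* **Diagonal** is forced to 100 on construction; threshold networks never
  contain self-loops, and p = 1 keeps the bootstrap degenerate-proof.
* **Duplicate pair records** (multiple local alignments in BLAST output)
  keep the maximum percent identity; absent pairs default to 0 (no
  detectable homology ⇒ no edge at any σ ≥ 1).
* **Thresholding** uses ≥ on stored real scores; σ is integer.
* **c<sub>i</sub> = 0** for degree < 2, keeping *C* an average over all n
  nodes.  ⟨d⟩ and *D* are over connected pairs only.
* **Betweenness** uses Brandes fractional counting, endpoints excluded,
  normalized by n(n−1)/2.  Under this normalization the edge values summed
  over all edges equal ⟨d⟩ on a connected graph (each shortest path of
  length ℓ crosses ℓ edges) — asserted as an invariant.
* **Assortativity** is Newman's degree–degree Pearson correlation, defined
  as 0 when degenerate (no edges / constant degree); per-node relative
  excess neighbor degrees are exposed separately because a per-node
  "assortativity" has no standard definition.
* **Fractal dimension** uses greedy first-fit coloring of the
  distance-≥ l<sub>B</sub> conflict graph in sorted-label order, box sizes
  l<sub>B</sub> = 1 … D, least-squares slope of log N<sub>B</sub> vs
  log l<sub>B</sub>.  The full-range fit is biased low on graphs whose
  diameter barely exceeds the scaling regime (an 8×8 lattice fits ≈ 1.42);
  tests therefore assert the 2-D range on a 20×20 lattice and only the
  dimension *ordering* on small ones.  Values should be compared across
  networks computed with this same heuristic, not read as absolute.
* **NG tie tolerance**: betweenness values within 1e−9 (relative) count as
  tied; exact ties then resolve lexicographically.
* **Edge betweenness inside the removal loop** is computed with igraph's C
  implementation for speed (~200 recomputation sweeps per 42-node network;
  1000 bootstrap replicates in ~15 s); everything it feeds — removal
  policy, event log, dendrogram, supports — is implemented here, and the
  slow-path oracles in the test suite enumerate shortest paths explicitly.
* **Degenerate inputs**: edgeless graphs raise for path statistics and are
  still processed by the bootstrap (all non-trivial branches simply score
  absent); n < 2 refuses to scan; overlapping or non-covering partitions,
  mismatched node sets, and out-of-range scores raise typed errors.

## Open design points, as resolved

* Percent identity from multiple HSPs per pair is not standardized by
  aligners; the max rule is deterministic and conservative toward
  homology.
* Whether the "critical network" lies on the lower or upper side of the δ
  peak is conventionally ambiguous; the lower side (the last σ before the
  reorganization) is used, which is the connected network that still
  contains the inter-community boundary edges.
* "Co-assignment" in the congruence index is undefined when community
  labels differ between methods; the optimal one-to-one matching reduces
  to the intuitive count whenever partitions agree, and is symmetric.
* Branch "featured in a replicate" means exact node-set identity against
  any branch of the replicate's dendrogram — stricter and more
  deterministic than matching only the replicate's best partition.
  Support monotonicity along nested branches is *not* guaranteed by NG
  replicates and is not asserted.
* One edge is removed per betweenness recomputation (classic NG), not all
  tied edges at once.

## Problem sizes

Default test and acceptance runs use 36–42-node matrices, 101-threshold
scans, and 100–1000 bootstrap replicates at 4944 trials; the exhaustive
metric cross-checks run over every graph on ≤ 6 nodes (networkx graph
atlas) plus seeded random 7–8-node graphs.  These sizes were chosen to
match the scale of the motivating dataset while keeping the full suite in
seconds.

## Known limitations

* Absolute δ values are normalization-dependent (only peak locations are
  invariant, which is all the method uses).
* Greedy box covering gives an upper bound on N<sub>B</sub>; d<sub>b</sub>
  is heuristic-dependent.
* The bootstrap resamples matrix entries independently; real character
  resampling induces correlations between entries sharing sequences,
  which this ignores (the variance *profile* is matched, not the joint
  distribution).
* Exact-set branch scoring is conservative: one misplaced sequence in a
  replicate counts the whole branch as absent.
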