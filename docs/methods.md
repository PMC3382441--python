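# Methods

## The duplication–loss model

A species tree S is rooted, binary, uniquely leaf-labeled by the species
set; we treat its node set as an upper semilattice with join `a + b` (the
lca) and top element ⊤ (the root).  The primitives used throughout:

* **D(a, b)** — comparability: 1 iff a and b lie on one root-to-leaf path;
* **ρ(a, b)** — number of edges on the path between a and b;
* **Sb(a, b)** — the lineages branching off that path, by the three-case
  recurrence (empty for equal nodes or siblings; otherwise walk the lower
  endpoint upward collecting its sibling; swap arguments when needed);
* **L(a, b) = |Sb(a, b)| = ρ(a, b) − 2(1 − D(a, b))** — the loss count.

For a rooted gene tree (duplicate leaf labels allowed) the lca-mapping M is
computed leaf-up.  An internal node v with children w₁, w₂ contributes
κᴰ(v) = D(M(w₁), M(w₂)) duplications and κᴸ(v) = L(M(w₁), M(w₂)) losses;
these per-node contributions are provably the sums over species of the
elementary duplication/loss cost functions, and their totals are the
minimal event counts of any embedding of the gene tree into S.  The
weighted mutation cost is α·dups + β·losses with α, β > 0.

Implementation notes: species-tree nodes carry leaf-cluster bitmasks, so
D is a subset test and ρ a depth formula; lca queries go through an Euler
tour + sparse table (O(|S| log |S|) build, O(1) query).  Duplication and
loss counts are exact integers; only the weighted total is a float.

## Unrooted reconciliation

A rooting G_e of an unrooted gene tree subdivides edge e with a new root.
To score all rootings at once the tree is doubled into arcs; arc ⟨v, w⟩
carries the lca of the species below the leaves on v's side.  Two tree
traversals (inward, then outward) compute all 2|E| labels.

Before labeling, the species tree is *conceptually* restricted to the
subtree rooted at the lca of the gene tree's labels — every rooting then
maps its root to the restricted top ⊤, with no change of cost.  The
implementation does not materialize the restriction: it simply passes that
lca around as `top`, since all mappings stay below it and D/L/ρ are
path-local.

With the labels in hand:

* the cost of the rooting at e decomposes into per-node contributions that
  depend only on each node's *parent direction*; a rerooting sweep
  (the same two traversals) accumulates these sums F⟨v,w⟩ for every arc,
  and σ_e = F⟨u,v⟩ + F⟨v,u⟩ + the root's own D/L of the two arc labels.
  This yields every σ_e, hence Min_G and the optimum, in O(max(|G|,|S|));
* an edge is *symmetric* when zero or two of its arc labels equal ⊤;
  each internal node's star falls into one of five types S1–S5 by the
  count of ⊤ labels on its three incoming/outgoing arcs.  The classifier
  raises rather than guess if a labeling matches none (provably impossible
  for valid inputs; a failure would indicate a labeling bug).  The
  structural facts — several optimal edges all lie in S4/S5 stars (M1),
  a unique optimal edge is symmetric in an S2/S3 star (M2), two S2 stars
  share an edge (C1) — are asserted as test invariants on every random
  instance rather than used to compute Min_G.

`brute_force_optimal` roots the tree at every edge and reconciles from
scratch through the rooted-tree code path; it is kept deliberately naive
and code-independent of the sweep, as the oracle for randomized testing.

Degenerate inputs: a 2-leaf gene tree has a single edge and no stars; the
sweep handles it uniformly (the rooting cost is just the root node's D/L).
A gene tree whose labels are all one species restricts ⊤ to a species leaf;
all arcs then carry ⊤ and every edge is optimal, again with no special
casing.

## Constant-time NNI maintenance

An NNI on center edge e₀ = {x, y} views the tree as ((T₁,T₂),(T₃,T₄)) and
swaps T₁ with T₃; the second interchange per edge is the same move after
renaming the two subtrees at x, which is how frames are generated (ordered
deterministically by edge id, `variant` 0/1).  Side edges keep their Edge
identity through the rewiring, so lengths — and hence weak-edge
eligibility — follow the edge.

Per move:

* **labels**: only the two center arcs change; they are recomputed with two
  lca queries (the four side arcs keep their values and are re-keyed to the
  new endpoints);
* **Min_G**: a nine-case local analysis over C = {e₀, e₁…e₄}.  EQ1 (Min
  disjoint from C), EQ2 (Min ⊇ C, every semi-alternating pair contains a
  symmetric edge), EQ3 (Min is exactly the center), EQ4 (Min ∩ C one side
  edge, center asymmetric after) leave Min unchanged; NE1 removes the
  all-asymmetric semi-alternating pair from C; NE2 (one side edge, center
  symmetric after) adds the post-move star of the center and that edge;
  NE3/NE4/NE5 handle Min ∩ C being a full pre-move star, keyed by the
  symmetry of its side edges and of the post-move center.  Where the case
  statement leaves a choice open (the star adjoined in NE2), the
  implementation takes the star containing the transformed optimal edge,
  the reading consistent with the S5 structure of that star; the
  randomized-walk oracle confirms it.
* **cost**: if the center rooting is optimal before and after, the cost
  moves by Δ₄(a₁,a₂,a₃,a₄), where
  φ(a,b,c) = α(D(a,b) + D(a+b,c)) + β(L(a,b) + L(a+b,c)),
  φ′(a,b,c,d) = φ(a,b,c+d) + αD(c,d) + βL(c,d), and
  Δ₄(a,b,c,d) = φ′(a,d,b,c) − φ′(a,b,c,d).  Otherwise a surviving optimal
  edge lies in some Tᵢ ∪ {eᵢ} and the difference is the i-indexed
  Δ₃(a,b,c) = φ(c,b,a) − φ(a,b,c) form ((a₄,a₃,a₂), (a₃,a₄,a₁),
  (a₂,a₁,a₄), (a₁,a₂,a₃) for i = 1…4).  For EQ1 the surviving subtree is
  located in O(1) by following the direction of the non-⊤ arc labels,
  which point toward the optimal region.

A configuration matching no case triggers a logged fallback to full
recomputation.  The test suite performs thousands of random-walk steps
comparing every maintained quantity against from-scratch recomputation and
requires **zero** fallback events and exact equality throughout; all nine
cases are exercised (case frequencies are tallied on the state).

Undo tokens restore topology, labels, Min_G and σ bit-identically, which
the depth-first neighborhood search relies on.

## Error correction and curation

σ_{α,β,k}(S, G) is the minimum cost over all trees reachable from G by at
most k NNIs whose centers are *eligible*: all internal edges, or, given ω,
the internal edges with length strictly below ω ("weak"; edges without a
length are never weak — treating a missing length as 0 would silently mark
nothing-or-everything weak depending on ω, so absence means "not
measurable").  The search enumerates NNI sequences depth-first with
apply/undo; edges remain eligible across steps because eligibility is
attached to edge identity.  Duplicate topologies along different sequences
are not deduplicated — at desk scale they only cost time, and skipping
canonical-isomorphism checks preserves the O(lᵏ) enumeration envelope.
Ties between equally cheap corrections prefer the shorter NNI sequence,
then the lexicographically smallest canonical bipartition encoding, making
reports deterministic.

k = 0 reduces exactly to plain unrooted reconciliation.  A tree "has
errors" when some non-empty sequence strictly beats its uncorrected cost.
`knnic_total` sums corrected costs over a collection; `filter_by_mu`
rejects trees with more than μ weak edges (the curation filter used before
supertree runs).

## Supertree search

The kNNIST objective is minimized by a randomized-restart hill climb.
Design choices (the move set, start strategy and stopping rule are
genuinely open):

* **moves**: all rooted-NNI rearrangements plus all rerootings of the
  candidate's unrooted shape — the minimal complete local move set that can
  both reshape the tree and move its root, which matters because the
  objective depends on the species-tree root; `moves="spr"` adds rooted
  subtree-prune-regraft for harder instances;
* **starts**: uniform random rooted topologies (sequential leaf insertion
  at a uniformly chosen edge), 20 restarts by default;
* **descent**: strict best-improvement, ties broken by canonical order; no
  sideways moves, so every trajectory strictly decreases and terminates.
  All distinct final trees are ranked by cost and all co-optimal finals
  reported.

Candidates are memoized by canonical form, and candidate evaluation uses a
cost-only correction path (no report assembly).  With a fixed seed the
search is bit-reproducible.

## The simulator

`simulate` generates the study conditions the correction method assumes:

* **species trees**: uniform random rooted topologies, n_taxa = 8 by
  default (single-letter labels up to 26 taxa);
* **gene families**: a constant-rate birth–death walk down the species
  tree, dup_rate = loss_rate = 0.1 events per lineage per branch (each
  species branch spans one time unit).  These defaults keep the expected
  mutation cost per family small — the premise of error correction is that
  gene trees are nearly correct.  Families losing all lineages are
  resampled with a bounded retry budget.  No transfer, conversion or
  population-level coalescence is modeled;
* **branch lengths** on the emitted unrooted trees: log-normal body
  (median 0.4, σ_log = 0.5) with a short regime — 25% of internal edges
  drawn uniformly from [0.001, 0.02) — so an ω threshold of 0.05 separates
  the regimes crisply.  Lengths emulate ML branch-length estimates only in
  the one property the method consumes (short ⇒ suspect); they are not
  time-consistent with the birth–death walk;
* **errors**: NNIs at random edges below the threshold, returned as an
  explicit move list so tests can verify the truth stays reachable.

What passing recovery tests shows — and what it does not: on this
generator, one weak-edge NNI correction restores the true tree's cost in
roughly 95% of families (93–98% across seeds) and never does worse (the
reverse move is always in
the searched neighborhood), and 20-restart hill climbs recover the true
8-taxon species topology from 30 clean families.  Real gene trees violate
the generator's assumptions in known ways (errors not confined to short
branches, non-independent families, alignment artifacts), so these rates
certify the algorithms, not the biology.

## Problem sizes and tolerances

Randomized validation uses species trees up to 16–32 taxa and gene trees
up to 24 leaves, 500 instances for the sweep-vs-brute-force oracle, 100
fixtures × 50 steps for the NNI walks, 100 replicates for error-injection
recovery, and 3 seeded replicates × 20 restarts (30 families, 8 taxa) for
species-tree recovery; these sizes exercise every code path and keep the
full suite fast.  All equality assertions on costs are exact (`==`), not
approximate: with the weightings used (integers and halves), every cost and
every Δ is an exactly representable float, and the incremental updates are
required to reproduce recomputation bit-for-bit.

## Known limitations

* Only the weighted duplication–loss cost: no deep-coalescence or
  transfer-aware variants, no duplication-episode clustering.
* Species trees must be binary and uniquely labeled; gene leaves must map
  into the species set (no contraction of unsampled species).
* kNNIST is solved heuristically; no optimality certificate and no clade
  support values on the reported supertrees.
* The k-NNI search enumerates sequences, so runtime grows as (2l)ᵏ in the
  number of eligible edges; k ≤ 3 is the practical regime the tool targets.
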