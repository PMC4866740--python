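# Methods

## Model and assumptions

The detector operates on simple, undirected, unweighted graphs. Its
central assumption is the standard one for assortative community
structure: members of a community share more neighbours and more links
with each other than with the rest of the network. Three quantities drive
every decision:

* **Mutual neighbour score** `MNS(x, y) = |N(x) ∩ N(y)|`, computed for
  adjacent pairs only. Restricting to adjacent pairs keeps construction
  near-linear in `m` and is sufficient because both seeding phases only
  ever compare a node with its neighbours.
* **Membership conditions.** A candidate with `ℓ` links into a community
  whose minimum per-member intra-link count is `q` passes condition 1 if
  `ℓ > q`, 2 if `ℓ ≥ q`, 3 if `ℓ > q/2`, 4 if `ℓ ≥ q/2`. The halved
  thresholds are compared exactly (`2ℓ` vs `q`), never rounded.
* **Capacity** of a grouped node = inter-community links / degree, where
  links to solo (unassigned) nodes count as inter-community — a member's
  degree decomposes into intra-community links and everything else, with
  no third category. The **acceptance capability** of community `c` for
  node `v` is the sum of capacities of `v`'s neighbours inside `c`; it
  breaks ties between equally voted communities. Capability comparisons
  use exact rational arithmetic so that two genuinely equal sums are
  recognised as a tie regardless of float rounding.

Merging community A into B requires `inter_AB / n_B > α · intra_A / n_A`
strictly, with `α ∈ (0, 1]`; the comparison is evaluated in exact
rationals so the 0.1-step α grid can never flip a decision through float
error. Targets are scanned smallest-first and candidate absorbers in
descending shared-link count, ties by community identifier — an ordering
chosen (the underlying procedure does not fix one) so that small fragments
are absorbed first and the scan is deterministic. A target takes the first
absorber that passes, and scanning repeats until a full pass performs no
merge.

## Determinism

Every ordering is total: node sequences sort by degree with the canonical
node order (numeric when all identifiers parse as integers, else
lexicographic) as the final key; community sequences sort by size or link
count with the community identifier as the final key; community
identifiers themselves are allocated in canonical order. Consequently two
runs on the same graph — including runs from edge lists in different line
orders — produce byte-identical membership tables. This property is
enforced by tests over fixtures and dozens of random graphs.

Reallocation passes can, on graphs with very weak structure, enter a short
limit cycle (a node or a few flipping between equally attractive
placements on alternate sweeps). Each pass therefore fingerprints its
label state per sweep and stops at the first revisited state, which is as
deterministic as a fixed point; a hard sweep cap (100·n) remains as a
safety valve that raises a diagnostic error rather than returning
silently.

## Pipeline choices

* Part 3 runs admission passes 1→2→3, each followed by a reallocation
  pass: the eviction-style pass with condition 1 before the subgraph
  recursion, with condition 3 after it.
* The subgraph recursion (part 4) triggers at ≥ 10 residual solo nodes and
  runs at most once; 1–9 residual solo nodes proceed directly to part 5.
* Part 5 relaxes admission in the order 4 → 5 → 6 → 7 (decreasing
  restrictiveness), each followed by the non-evicting reallocation pass;
  any node still solo joins its highest-capability adjacent community, and
  nodes with no grouped neighbour (isolated nodes included) become
  singleton communities, so the output partition is always total.
* Part 6 lowers α from 1.0 in steps of 0.1, reallocating after each merge
  with the fully non-destructive pass (no evictions, two-node communities
  permitted) so totality is preserved, and tracks the best modularity
  seen; when a round drops below that best, the best state is restored and
  the sweep ends. The returned partition therefore never has lower Q than
  the partition entering part 6.

## Benchmark generators

All generators build edges by stub matching: stubs are shuffled and paired
greedily, incompatible pairs are re-paired, and residual stubs are settled
by degree-preserving edge swaps, with a small dropped remainder when no
legal placement exists. Instances are reproducible from (spec, seed); RNG
streams are seeded through a hash-salt-free digest of the parameters.

* **GN**: 128 nodes, four groups of 32, degree 16. Each node gets
  `round((1−μ)·16)` intra-group stubs and the complement inter-group, so
  degrees are exactly 16; on the 0.1 grid the complement equals
  `round(μ·16)`. The realised mixing is therefore quantised (e.g. 0.125
  at nominal μ = 0.1).
* **LFR**: degrees from a truncated power law (exponent γ, maximum
  `maxk`) whose lower cutoff is solved by bisection to hit the target mean
  degree; community sizes from a truncated power law (exponent β) drawn
  until they cover `N`, with the overshoot trimmed. Nodes are placed
  largest-intra-degree first into communities that can host them
  (intra-degree ≤ size − 1). Per-node intra stubs are
  `round((1−μ)·degree)`; any intra stubs that cannot be realised shift to
  the inter pool, except at μ = 0 where leftovers are dropped — the
  planted partition must have zero mixing, and a slight degree shortfall
  is preferable to a crossing edge. Realised mean degree stays within 10%
  of the target and realised mixing within ±0.02 of μ (checked by tests).
  The eight named parameterisations (S/B × SK/LK × SC/LC) cover 1000- and
  5000-node networks, mean degrees 10/20, community sizes 10–50/20–100,
  γ = 2, β = 1, maxk = 50.
* **Relaxed caveman**: 512 nodes in 16 cliques; a fraction D of each
  clique's edges is removed and rewired from a surviving endpoint to a
  uniformly chosen node of another community. Community sizes follow a
  truncated power law on [2, 157] whose exponent is calibrated (≈ 1.05)
  so the expected total is 512 — an exponent of 2 on that support has mean
  ≈ 8.8 and cannot reach a 32-node average — with one stratified draw per
  probability sixteenth, so each instance spans tiny communities through a
  near-cap giant, and ±1 adjustments land the sum exactly. An explicit
  16-entry size vector can be supplied instead.

What the generators do **not** emulate: degree–community correlations
beyond the stub construction, overlapping or hierarchical structure,
weighted or directed edges, and the exact wiring of any reference
implementation — comparisons against published numbers for these
benchmarks are therefore distributional, not graph-identical. Passing
recovery tests on them demonstrates behaviour under idealised planted
structure, not performance on real-world networks, whose hubs, skews and
noise differ.

## Metrics

Entropies use natural logarithms (NVI and NMI are base-invariant ratios).
NVI divides the variation of information by `log n`; for `n = 1` it is
defined as 0. NMI is the confusion-matrix form `2·I/(H(X)+H(Y))`; when
both partitions are the single-community partition the 0/0 ratio is
defined as 1 (the partitions are identical). Modularity is computed per
community as `m_c/m − (D_c/2m)²`; it is 0 for the single-community
partition and can be negative for adversarial partitions, so only the
upper bound Q ≤ 1 is asserted. Modularity density weighs each community
term by its internal density `d_c = 2·m_in/(n_c(n_c−1))` — defined as 0
for singletons to stay finite — and subtracts the pairwise split penalty
`(m_cc'/2m)·(m_cc'/(n_c n_c'))` for each ordered community pair.

## Numerical and degenerate-input choices

* Self-loops and duplicate edges are dropped on read, with warnings;
  empty graphs and malformed lines are errors.
* Isolated nodes bypass propagation and are emitted as singleton
  communities.
* The one-shot pruning stage of the first reallocation pass evicts members
  whose intra-link count is below their community's first quartile
  (numpy's linear-interpolation percentile), decided on a snapshot taken
  before any eviction in that community.
* Degree-0 capacity is 0 by convention.

## Problem sizes used in validation

The bundled validation uses desk-scale instances: 1000-node LFR networks,
the 512-node relaxed-caveman family, the 128-node GN family, recovery
checks over 10 seeds and threshold scans over 5 seeds per grid point, and
determinism checks over ~50 random graphs of 20–60 nodes. These sizes
exercise every code path while keeping a full run in the minutes range on
a single core; all generators accept larger parameters.

## Known limitations

* Trivial detection: beyond family-dependent mixing/degradation levels the
  output collapses to one community (observed at μ ≈ 0.5 on GN, D ≈ 0.5
  on the relaxed caveman, μ ≈ 0.6–0.7 on 1000-node small-community LFR);
  this mirrors the behaviour of the unconstrained algorithm and is
  reported, not suppressed.
* The two-community split found for the Zachary karate network has
  modularity 0.372 — the canonical two-faction value; published
  modularities for other detectors on this network are higher because they
  split it into more than two communities.
* Sequential only; no incremental updates for dynamic graphs.
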