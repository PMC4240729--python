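# Methods

## Model and conventions

A genome is a permutation of `1..n` (`n ≥ 2`); a genome class is the
unordered pair `{π, reversed(π)}` with the lexicographically smaller
orientation as canonical representative (deterministic equality and
hashing).  Adjacency sets are stored as frozensets of `(min, max)`
pairs, giving unordered-pair semantics with cheap set algebra.  The
breakpoint distance `d(x,y) = n − 1 − |A(x) ∩ A(y)|` is a pseudometric
on permutations and a metric on classes.

Composition follows `(x∘z)_i = x_{z_i}`.  Under this convention
left-composition relabels gene values through `z`, maps both adjacency
sets by the same bijection, and therefore preserves the distance:
`d(zx, zy) = d(x, y)`, equivalently `d(x, y) = d(id, x⁻¹y)`.  The
position-shuffling side `x ↦ xz` does *not* preserve the distance (the
distance is a function of `y⁻¹x`, and conjugation does not fix it);
only the relabeling invariance is claimed, tested, and used — it is all
the uniform-sampling symmetry argument needs.

## Exhaustive engine

All exhaustive operations (class enumeration, patch oracles, brute-force
medians, closures) run over a cached table of the `n!/2` classes with
each adjacency set packed into a 64-bit mask (one bit per edge of `K_n`;
`C(8,2) = 28` bits at the cap).  Distances become popcounts and patch
membership two bitwise comparisons, vectorized with numpy over the whole
table.  The enumeration cap defaults to `n = 8` (20,160 classes); every
capped entry point raises a resource error beyond it rather than
silently thrashing.

## Geodesic patches

Membership in `[x,y]̄` has two equivalent characterizations — distance
additivity through `z`, and the adjacency sandwich
`A(x)∩A(y) ⊆ A(z) ⊆ A(x)∪A(y)`.  Both are implemented and their
equivalence is a test (exhaustive at `n = 5`, randomized at 6, 7), not
an assumption.  Patch enumeration has two independent routes:

* **oracle** — filter the class table by the sandwich test;
* **hampath** — depth-first enumeration of Hamiltonian paths of the
  graph `A(x) ∪ A(y)` constrained to use every edge of `A(x) ∩ A(y)`,
  deduplicated by class.  A branch is pruned as soon as a required edge
  has both endpoints placed without being traversed.  The union graph of
  two genomes has maximum degree 4, so the search is far smaller than
  the `n!/2` scan and extends beyond the cap.

The two routes are cross-checked exhaustively for all pairs at `n = 5`
and on random pairs at larger `n`.

`find_geodesic` demands full isometry with `[0..d]` — all pairwise
distances `|i − j|`, not just the endpoint relations — since that is
what makes a set a geodesic; the search runs level-by-level over patch
members (every geodesic point satisfies additivity), tie-broken by
canonical lexicographic order for determinism.  Only the union `[x,y]̄`
and membership are exposed; grouping members into individual maximal
patches is under-determined by the theory downstream of it and is not
implemented.

## Medians

Weighted genome sets collapse equivalent permutations and sum their
multiplicities, so median value and median set are invariant under
swapping any member for its reversal (tested by randomized flipping).
The brute-force solver scans the class table and always returns the
*full* argmin set — the object of interest is the median set, never an
arbitrary representative.

For pairwise maximally distant inputs (checked strictly — all `C(k,2)`
distances must equal `n − 1`, since the characterization is false
otherwise), `median_set_maxdist` enumerates Hamiltonian paths of the
adjacency-union graph; its value `(k−1)(n−1)` and its set are verified
against brute force for every constructible `(n, k)` with `n ≤ 7`.

## Accessibility

The accessible set `Z̄(X)` is computed as a fixed-point closure rather
than by enumerating hop chains: chains concatenate, so closing `X`
under the step "add `[c,y]̄` for any two reached points `c, y`" reaches
exactly the union of all iterated one-step sets.  `one_step_accessible`
keeps the anchors pinned to `X` (the definition of a single round);
`accessible_closure` lets them grow.  Pending point-pairs are processed
in vectorized batches against the class table; each unordered pair is
touched once, so the closure terminates after at most `|Z̄|²/2` patch
evaluations.  The conjecture report computes `M(X)` (brute force) and
`Z̄(X)` side by side and asserts only the proven containment
`Z̄(X) ⊆ M(X)`; equality is reported as data.

## Extremal constructions

Maximally distant sets are `k` edge-disjoint Hamiltonian paths of
`K_n`, feasible iff `k ≤ ⌊n/2⌋` (each path uses `n − 1` of the
`n(n−1)/2` edges, and that many paths exist).  Construction is by
seeded randomized backtracking with restarts; the one regime where
random search stalls — even `n` with `k = n/2`, a full path
decomposition — uses the classical round-robin zig-zag decomposition
composed with a seeded random relabeling (relabeling preserves
pairwise distances, keeping the output seed-dependent).  Every result
verifies its own pairwise distances before being returned.

The no-geodesic family pairs the identity with `1 2 σ n−1 n` for a
non-identity arrangement `σ` of `{3..n−2}` (`n ≥ 6`); an identity `σ`
is rejected since it gives the identity genome itself.

## Monte-Carlo experiments

Uniform classes are sampled as uniform permutations pushed onto classes
(both orientations equally likely, so the push-forward is uniform).
For the moments experiment the shared-adjacency count is computed
vectorized: against an identity reference it is the number of
consecutive entries differing by 1; for two random genomes, one genome
is relabelled through the other (distance invariance) reducing to the
same count.  The two conventions are equidistributed and both exposed.

Problem sizes were chosen so every exhaustive quantity is exact and
every stochastic band is wide relative to its Monte-Carlo error:

* moments: `n = 1000`, 20,000 replicates — standard error of the mean
  ≈ 0.01, an order of magnitude inside the ±0.1 band; the exact finite-n
  mean is `2 − 2/n` (verified by full enumeration at `n = 4`, where the
  pair law gives mean 1.5 and variance 7/12);
* tail convergence: grid `n ∈ {10, 100, 1000}` with `aₙ ∈ {√n, log(n+1),
  n}` — all divergent; a bounded sequence is rejected at configuration
  time since the convergence statements fail for it.  Only the
  first-vs-last tail comparison is asserted; the full trend is reported;
* median gap: `n = 7, k = 3`, 200 replicates with the exact brute-force
  median per replicate; the bound `0 ≤ e* ≤ C(k,2)·α` is deterministic,
  so it is asserted on *every* replicate, not on average;
* accessible distance: `n ≤ 6` closures per replicate; the per-sample
  two-sided bound `0 ≤ (k−1)(n−1) − d(z,X) ≤ C(k,2)·α` is likewise
  asserted per replicate.

Replicate streams are spawned from a single root `SeedSequence`
(per-replicate in the exact experiments, fixed 1000-replicate blocks in
the vectorized ones), so every experiment is bit-reproducible for a
fixed seed.  The asymptotic mean of the distance is `n − 3 + 2/n` up to
lower-order terms; the sign of the `1/n` correction is reported
empirically, not asserted.

## What the synthetic inputs do and do not show

All inputs are abstract permutations — uniform random genomes, seeded
extremal constructions, and the small worked examples.  Uniform
sampling matches the model under which the asymptotic results are
stated, but real gene orders are not uniform: related genomes share
long conserved segments, so their distance sits far below `n − 1` and
the maximally-distant median structure studied here describes the
*saturated* regime (little or no shared signal), not closely related
species.  Passing tests certify the combinatorics and the asymptotic
statements, not biological realism of any particular genome set.
Unequal gene content, signed genes, circular or multichromosomal
genomes are out of scope throughout.

## Known limitations

* Exhaustive operations stop at `n = 8`; no heuristic or ILP median
  solver is provided for larger `n`, so the random-median experiments
  are exact but small-n.
* The accessibility closure stores patch results transiently; a repeated
  fixed-point check on a large instance recomputes pairs rather than
  caching them (memory kept flat in exchange).
* For odd `n` near the `⌊n/2⌋` feasibility bound the randomized
  constructor has slack but no closed form; failures raise with
  diagnostics rather than being silently retried forever.
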