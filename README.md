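# bpmedian

Breakpoint distance, geodesic patches, and median sets for unsigned
linear unichromosomal genomes.

## The problem

In comparative genomics a genome with `n` genes is modelled as a
permutation of the labels `1..n`; reading the chromosome in either
direction gives the same molecule, so the object of study is the class
`{π, reversed(π)}` (there are `n!/2` of them).  The **breakpoint
distance** between two genomes counts the gene neighborhoods they do
not share:

```
d(x, y) = (n − 1) − |A(x) ∩ A(y)|
```

where `A(x)` is the set of *adjacencies* of `x` — the unordered pairs of
genes that are consecutive in `x`.  On classes this is a metric, but the
space is **not geodesic**: between some pairs there is no chain of
genomes realizing every intermediate distance.  The substitute is the
**geodesic patch**; the union of all patches between `x` and `y` is

```
[x,y]̄ = { z : A(x) ∩ A(y) ⊆ A(z) ⊆ A(x) ∪ A(y) }
       = { z : d(x,z) + d(z,y) = d(x,y) }.
```

The **median** of `k` genomes minimizes the total breakpoint distance
to them — the archetypal ancestral-genome estimation problem.  For
inputs that are pairwise maximally distant (`d = n − 1`, disjoint
adjacency sets) the theory is sharp:

* the median value is exactly `(k − 1)(n − 1)`, and `m` is a median iff
  `A(m) ⊆ ∪ᵢ A(xᵢ)` — which turns exact median enumeration into
  Hamiltonian-path enumeration of the adjacency-union graph;
* every genome *accessible* from the inputs by iterated patch-hopping
  (the closure `Z̄(X)`) is a median, and patches between medians contain
  only medians;
* for `k` *random* genomes the same picture holds asymptotically: the
  shared-adjacency count of a random pair has mean and variance near 2,
  so the median value gap `e* = (k−1)(n−1) − mₙ(X)` obeys the
  per-sample bound `0 ≤ e* ≤ C(k,2)·α` with `α` the largest pairwise
  shared-adjacency count, and `e*/aₙ → 0` for any divergent `aₙ`.

`bpmedian` implements all of this: the pseudometric/metric machinery,
patch membership and enumeration (two independent methods), geodesic
search, exact median solvers, accessibility closures, constructors for
maximally distant sets and for the no-geodesic family, and Monte-Carlo
experiments for the random-genome statements.

## Worked example

The six-gene genome `1 3 5 2 4 6` shares no adjacency with the
identity, so it sits at the maximum distance 5 — yet a geodesic
happens to exist between them:

```
$ printf '1 2 3 4 5 6\n1 3 5 2 4 6\n' > pair.txt
$ bpmedian patch pair.txt --find-geodesic
# d = 5; |[x,y]-bar| = 28
1 2 3 4 5 6
1 2 3 4 6 5
...
# geodesic of length 5:
1 2 3 4 5 6
1 2 3 4 6 5
1 2 3 5 6 4
1 2 4 6 5 3
1 3 5 6 4 2
1 3 5 2 4 6
```

28 classes lie on patches between the pair; the chain printed realizes
every distance 0..5 (each step cuts one adjacency and rejoins).  By
contrast `1 2 4 3 5 6 7` vs the identity has **no** geodesic
(`bpmedian patch --find-geodesic` reports it), the smallest instance of
a whole family witnessing non-geodesicity.

Three pairwise maximally distant seven-gene genomes and their exact
median set:

```
$ bpmedian construct --n 7 --k 3 --seed 1 -o mds7.txt
$ bpmedian median mds7.txt --method maxdist --accessible --conjecture-report
# median value = 12; |M| = 912 (maxdist_hampath)
...
# |Z-bar| = 912
# conjecture report: {"n": 7, "k": 3, "median_value": 12, "n_medians": 912,
#                     "n_accessible": 912, "n_missing": 0, "equal": true}
```

The median value is `(3−1)(7−1) = 12`, attained by 912 of the 2520
classes — including the three inputs themselves.  On this instance the
accessibility closure reaches *every* median (`equal: true`); whether
that always holds is an open question the report tracks without
asserting.

Random-genome statistics at `n = 1000`:

```
$ bpmedian simulate --experiment moments --n 1000 --reps 20000 --seed 1
{ "mean_eps": 2.0069, "var_eps": 2.0196, "mean_d": 996.9931, ... }
```

Both moments of the shared-adjacency count sit near the asymptotic
value 2: two random genomes are nearly maximally distant, which is why
the median of random genomes behaves like the maximally-distant case.

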