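"""Breakpoint medians: total distance, exact median sets, accessibility.

The median problem asks for the genome(s) minimizing the total bp distance
to k given genomes; the minimum is the *median value* and the argmin set
the *median set*.  Everything here operates on genome classes, where bp
distance is a true metric, and supports integer multiplicities (weights
collapse over equivalent permutations).

For inputs that are pairwise maximally distant (d = n-1 for every pair,
i.e. pairwise disjoint adjacency sets) the median value is exactly
(k-1)(n-1) and the median set has a closed characterization: m is a median
iff every adjacency of m appears in some input.  That turns exact median
enumeration into Hamiltonian-path enumeration of the adjacency-union
graph — no brute force needed — while the brute-force solver remains as an
independent oracle for small n.

Accessibility: starting from X, repeatedly hop onto geodesic patches
between a point already reached and an input (or, in later rounds, any
two points already reached).  The set of everything reachable this way,
Z-bar(X), is computed as a fixed-point closure; for maximally distant X it
is provably contained in the median set, and whether the containment is an
equality is an open question this module reports on rather than asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence

import numpy as np

from . import _classtable as ct
from .genome_core import (
    ENUMERATION_CAP,
    GenomeClass,
    GenomeInputError,
    GenomeLike,
    ResourceLimitError,
    bp_distance,
    class_of,
)
from .geodesic import hamiltonian_paths, patch_union_set

__all__ = [
    "WeightedGenomeSet",
    "MedianResult",
    "ConjectureReport",
    "total_distance",
    "median_bruteforce",
    "is_median_maxdist",
    "median_set_maxdist",
    "one_step_accessible",
    "accessible_closure",
    "conjecture1_report",
]


class WeightedGenomeSet:
    """A finite multiset of genome classes with positive integer weights.

    Equivalent input permutations collapse onto one class with their
    weights summed, so every derived quantity (total distance, median
    value, median set) is invariant under replacing any member by its
    reversal.
    """

    def __init__(
        self,
        genomes: Iterable[GenomeLike],
        weights: Iterable[int] | None = None,
    ):
        gs = [class_of(g) for g in genomes]
        if not gs:
            raise GenomeInputError("a weighted genome set must be nonempty")
        ns = {g.n for g in gs}
        if len(ns) != 1:
            raise GenomeInputError(f"mixed genome lengths {sorted(ns)}")
        ws = [1] * len(gs) if weights is None else [int(w) for w in weights]
        if len(ws) != len(gs):
            raise GenomeInputError("weights must parallel genomes")
        if any(w <= 0 for w in ws):
            raise GenomeInputError("weights must be positive integers")
        acc: dict[GenomeClass, int] = {}
        for g, w in zip(gs, ws):
            acc[g] = acc.get(g, 0) + w
        self._weights = dict(
            sorted(acc.items(), key=lambda kv: kv[0].representative.genes)
        )
        self._n = ns.pop()

    @property
    def n(self) -> int:
        return self._n

    @property
    def classes(self) -> tuple[GenomeClass, ...]:
        return tuple(self._weights)

    @property
    def weights(self) -> Mapping[GenomeClass, int]:
        return dict(self._weights)

    def multiplicity(self, g: GenomeLike) -> int:
        return self._weights.get(class_of(g), 0)

    @property
    def total_weight(self) -> int:
        return sum(self._weights.values())

    def items(self) -> Iterator[tuple[GenomeClass, int]]:
        return iter(self._weights.items())

    def __len__(self) -> int:
        return len(self._weights)

    def __iter__(self) -> Iterator[GenomeClass]:
        return iter(self._weights)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedGenomeSet) and self._weights == other._weights
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"{g}:{w}" for g, w in self._weights.items())
        return f"WeightedGenomeSet({{{inner}}})"


def _as_weighted(A: WeightedGenomeSet | Iterable[GenomeLike]) -> WeightedGenomeSet:
    if isinstance(A, WeightedGenomeSet):
        return A
    return WeightedGenomeSet(A)


@dataclass(frozen=True)
class MedianResult:
    """Median value and full median set of a weighted genome set."""

    value: int
    medians: frozenset[GenomeClass]
    method: Literal["bruteforce", "maxdist_hampath"]

    @property
    def n_medians(self) -> int:
        return len(self.medians)


def total_distance(q: GenomeLike, A: WeightedGenomeSet | Iterable[GenomeLike]) -> int:
    """Weighted sum of bp distances from ``q`` to the members of ``A``."""
    A = _as_weighted(A)
    cq = class_of(q)
    if cq.n != A.n:
        raise GenomeInputError(f"mixed genome lengths {cq.n} and {A.n}")
    return sum(w * bp_distance(cq, g) for g, w in A.items())


def _totals_over_classes(A: WeightedGenomeSet, table: ct.ClassTable) -> np.ndarray:
    """Total weighted distance from every class in the table to A."""
    n = A.n
    totals = np.zeros(len(table), dtype=np.int64)
    for g, w in A.items():
        m = np.uint64(table.mask(g))
        totals += w * ((n - 1) - ct.popcount(table.masks & m).astype(np.int64))
    return totals


def median_bruteforce(
    A: WeightedGenomeSet | Iterable[GenomeLike], cap: int = ENUMERATION_CAP
) -> MedianResult:
    """Exact median value and median set by scanning all n!/2 classes."""
    A = _as_weighted(A)
    if A.n > cap:
        raise ResourceLimitError(
            f"brute-force median needs n <= {cap}, got n={A.n}"
        )
    table = ct.class_table(A.n)
    totals = _totals_over_classes(A, table)
    value = int(totals.min())
    medians = frozenset(table.cls(i) for i in (totals == value).nonzero()[0])
    return MedianResult(value=value, medians=medians, method="bruteforce")


def _check_maxdist(X: Sequence[GenomeClass]) -> int:
    n = X[0].n
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            d = bp_distance(X[i], X[j])
            if d != n - 1:
                raise GenomeInputError(
                    f"inputs must be pairwise at maximum distance {n - 1}; "
                    f"d({X[i]}, {X[j]}) = {d}"
                )
    return n


def _as_class_list(X: Iterable[GenomeLike]) -> list[GenomeClass]:
    out = [class_of(g) for g in X]
    if not out:
        raise GenomeInputError("need a nonempty set of genomes")
    ns = {g.n for g in out}
    if len(ns) != 1:
        raise GenomeInputError(f"mixed genome lengths {sorted(ns)}")
    return out


def is_median_maxdist(m: GenomeLike, X: Iterable[GenomeLike]) -> bool:
    """Median membership test for pairwise maximally distant inputs.

    ``m`` is a median of such an ``X`` iff A(m) is contained in the union
    of the inputs' adjacency sets; raises if ``X`` is not pairwise at
    distance n-1 (the characterization fails otherwise).
    """
    Xc = _as_class_list(X)
    _check_maxdist(Xc)
    cm = class_of(m)
    if cm.n != Xc[0].n:
        raise GenomeInputError(f"mixed genome lengths {cm.n} and {Xc[0].n}")
    union: frozenset = frozenset()
    for x in Xc:
        union |= x.adjacencies()
    return cm.adjacencies() <= union


def median_set_maxdist(X: Iterable[GenomeLike]) -> MedianResult:
    """Exact median set for pairwise maximally distant inputs.

    The median value is (k-1)(n-1); the median set is every class whose
    adjacencies all lie in the union graph of the inputs, enumerated as
    Hamiltonian paths of that graph.  Agrees with the brute-force solver
    whenever the latter is feasible.
    """
    Xc = _as_class_list(X)
    n = _check_maxdist(Xc)
    k = len(Xc)
    union: frozenset = frozenset()
    for x in Xc:
        union |= x.adjacencies()
    medians = frozenset(class_of(p) for p in hamiltonian_paths(n, union))
    return MedianResult(
        value=(k - 1) * (n - 1), medians=medians, method="maxdist_hampath"
    )


# ---------------------------------------------------------------------------
# accessibility


def _patch_closure(
    table: ct.ClassTable,
    seed: Sequence[int],
    anchors: Optional[Sequence[int]],
    chunk: int = 512,
) -> np.ndarray:
    """Fixed-point closure of ``seed`` under patch-hopping, as a boolean
    membership vector over the class table.

    With ``anchors`` given, each hop pairs a reached point with an anchor
    only (the one-step set Z(X)); with ``anchors=None`` hops pair any two
    reached points, which yields the full closure Z-bar (iterating
    Z_{r+1} = Z(Z_r) reaches the same fixed point, since a chain through
    two already-reached points is two rounds of one-step chains).
    """
    masks = table.masks
    in_c = np.zeros(len(table), dtype=bool)
    reached: list[int] = []
    pending_i: list[int] = []
    pending_j: list[int] = []

    def add(i: int) -> None:
        if in_c[i]:
            return
        in_c[i] = True
        if anchors is None:
            for j in reached:
                pending_i.append(i)
                pending_j.append(j)
        else:
            for j in anchors:
                if j != i:
                    pending_i.append(i)
                    pending_j.append(j)
        reached.append(i)

    for i in seed:
        add(int(i))
    while pending_i:
        bi = np.asarray(pending_i[:chunk], dtype=np.int64)
        bj = np.asarray(pending_j[:chunk], dtype=np.int64)
        del pending_i[:chunk], pending_j[:chunk]
        inter = (masks[bi] & masks[bj])[:, None]
        union = (masks[bi] | masks[bj])[:, None]
        mem = ((masks[None, :] & inter) == inter) & (
            (masks[None, :] | union) == union
        )
        for i in (mem.any(axis=0) & ~in_c).nonzero()[0]:
            add(int(i))
    return in_c


def _closure_sets(
    X: Iterable[GenomeLike], anchors_are_X: bool, cap: int
) -> tuple[ct.ClassTable, np.ndarray, list[GenomeClass]]:
    Xc = _as_class_list(X)
    n = Xc[0].n
    if n > cap:
        raise ResourceLimitError(f"accessibility closure needs n <= {cap}, got n={n}")
    table = ct.class_table(n)
    seed = [table.idx(g) for g in Xc]
    in_c = _patch_closure(table, seed, anchors=seed if anchors_are_X else None)
    return table, in_c, Xc


def one_step_accessible(
    X: Iterable[GenomeLike], cap: int = ENUMERATION_CAP
) -> frozenset[GenomeClass]:
    """Z(X): everything reachable by a chain of patch hops anchored in X.

    Chains start at a member of X and each hop lands on a geodesic patch
    between the current point and a member of X; computed as a fixed
    point, which is equivalent to enumerating finite chains.
    """
    table, in_c, _ = _closure_sets(X, anchors_are_X=True, cap=cap)
    return frozenset(table.cls(int(i)) for i in in_c.nonzero()[0])


def accessible_closure(
    X: Iterable[GenomeLike], cap: int = ENUMERATION_CAP
) -> frozenset[GenomeClass]:
    """Z-bar(X): the union of Z_r(X) over all rounds r.

    Satisfies Z(Z-bar(X)) = Z-bar(X); always contains X; for pairwise
    maximally distant X it is contained in the median set.
    """
    table, in_c, _ = _closure_sets(X, anchors_are_X=False, cap=cap)
    return frozenset(table.cls(int(i)) for i in in_c.nonzero()[0])


@dataclass(frozen=True)
class ConjectureReport:
    """Side-by-side census of the median set and the accessible set.

    Whether every median is accessible (M(X) = Z-bar(X)) is open; this
    report carries both sets and their one-sided difference and asserts
    nothing about equality.
    """

    n: int
    k: int
    median_value: int
    medians: frozenset[GenomeClass]
    accessible: frozenset[GenomeClass]

    @property
    def n_medians(self) -> int:
        return len(self.medians)

    @property
    def n_accessible(self) -> int:
        return len(self.accessible)

    @property
    def missing(self) -> frozenset[GenomeClass]:
        """Medians not accessible from X (empty iff the sets coincide)."""
        return self.medians - self.accessible

    @property
    def equal(self) -> bool:
        return self.medians == self.accessible

    def summary(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "median_value": self.median_value,
            "n_medians": self.n_medians,
            "n_accessible": self.n_accessible,
            "n_missing": len(self.missing),
            "equal": self.equal,
        }


def conjecture1_report(
    X: Iterable[GenomeLike], cap: int = ENUMERATION_CAP
) -> ConjectureReport:
    """Compare the exact median set with the accessibility closure.

    Requires pairwise maximally distant inputs (the regime where
    Z-bar(X) ⊆ M(X) is guaranteed) and n small enough for the brute-force
    median oracle.
    """
    Xc = _as_class_list(X)
    n = _check_maxdist(Xc)
    res = median_bruteforce(WeightedGenomeSet(Xc), cap=cap)
    acc = accessible_closure(Xc, cap=cap)
    return ConjectureReport(
        n=n,
        k=len(Xc),
        median_value=res.value,
        medians=res.medians,
        accessible=acc,
    )
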