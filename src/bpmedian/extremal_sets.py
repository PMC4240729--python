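"""Constructors for the special inputs the theory singles out.

Two families matter:

* *Maximally distant sets*: k genome classes pairwise at bp distance n-1,
  equivalently with pairwise disjoint adjacency sets — k edge-disjoint
  Hamiltonian paths of K_n.  Since K_n has n(n-1)/2 edges and each path
  uses n-1, at most floor(n/2) such classes exist (and that many do: K_n
  decomposes into floor(n/2) Hamiltonian paths).

* The *non-geodesic pair family*: the identity together with
  ``1 2 s n-1 n`` for a non-identity arrangement ``s`` of {3..n-2}.  No
  geodesic connects the two, witnessing that the class space is not a
  geodesic space.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_core import (
    GenomeClass,
    GenomeInputError,
    Permutation,
    bp_distance,
)

__all__ = ["MaxDistantSet", "InfeasibleConstructionError", "max_distant_set", "nongeodesic_pair"]


class InfeasibleConstructionError(ValueError):
    """Requested construction violates a counting bound."""


@dataclass(frozen=True)
class MaxDistantSet:
    """k genome classes of length n, pairwise at the maximum distance n-1."""

    classes: tuple[GenomeClass, ...]
    n: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __len__(self):
        return len(self.classes)

    def verify(self) -> None:
        for i in range(self.k):
            for j in range(i + 1, self.k):
                d = bp_distance(self.classes[i], self.classes[j])
                if d != self.n - 1:
                    raise AssertionError(
                        f"pair ({i},{j}) at distance {d}, expected {self.n - 1}"
                    )


def _random_ham_path(
    n: int, forbidden: set[tuple[int, int]], rng: random.Random, tries: int
) -> tuple[int, ...] | None:
    """One Hamiltonian path of K_n avoiding forbidden edges, by randomized
    backtracking DFS (neighbor order shuffled per node)."""

    def edge(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for _ in range(tries):
        start = rng.randrange(1, n + 1)
        path = [start]
        used = {start}
        budget = 50 * n * n  # backtracking steps before a fresh restart

        def extend() -> bool:
            nonlocal budget
            if len(path) == n:
                return True
            if budget <= 0:
                return False
            u = path[-1]
            cands = [
                w
                for w in range(1, n + 1)
                if w not in used and edge(u, w) not in forbidden
            ]
            rng.shuffle(cands)
            for w in cands:
                budget -= 1
                path.append(w)
                used.add(w)
                if extend():
                    return True
                path.pop()
                used.remove(w)
            return False

        if extend():
            return tuple(path)
    return None


def _zigzag_paths(n: int, k: int) -> list[tuple[int, ...]]:
    """First k paths of the round-robin decomposition of K_n, n even.

    Path j visits j, j+1, j-1, j+2, j-2, ... (mod n, labels shifted to
    1..n); the n/2 rotations are pairwise edge-disjoint — the classical
    scheduling construction.
    """
    out = []
    for j in range(k):
        path = [j]
        for i in range(1, n):
            step = (i + 1) // 2 if i % 2 else -(i // 2)
            path.append((j + step) % n)
        out.append(tuple(v + 1 for v in path))
    return out


def max_distant_set(n: int, k: int, seed: int = 0) -> MaxDistantSet:
    """Construct k pairwise maximally distant genome classes of length n.

    For even n with k = n/2 (a full path decomposition of K_n, where
    random search stalls) the classical round-robin decomposition is used
    under a seeded random relabeling of the genes; otherwise randomized
    backtracking over edge-disjoint Hamiltonian paths.  Deterministic for
    fixed (n, k, seed) and self-verifying.  ``k`` above floor(n/2) is
    rejected up front: k paths need k(n-1) distinct edges but K_n only
    has n(n-1)/2.
    """
    if n < 2:
        raise GenomeInputError(f"need n >= 2, got {n}")
    if k < 1:
        raise GenomeInputError(f"need k >= 1, got {k}")
    if k > n // 2:
        raise InfeasibleConstructionError(
            f"k={k} edge-disjoint Hamiltonian paths of K_{n} would need "
            f"{k * (n - 1)} distinct edges but K_{n} has {n * (n - 1) // 2}; "
            f"k <= floor(n/2) = {n // 2} is required"
        )
    rng = random.Random(seed)
    if n % 2 == 0 and k == n // 2:
        relabel = list(range(1, n + 1))
        rng.shuffle(relabel)
        classes = tuple(
            GenomeClass(Permutation(relabel[v - 1] for v in path))
            for path in _zigzag_paths(n, k)
        )
        out = MaxDistantSet(classes=classes, n=n, seed=seed)
        out.verify()
        return out
    for attempt in range(64):  # restart the whole greedy stack if it wedges
        used_edges: set[tuple[int, int]] = set()
        classes: list[GenomeClass] = []
        ok = True
        for _ in range(k):
            path = _random_ham_path(n, used_edges, rng, tries=256)
            if path is None:
                ok = False
                break
            for i in range(n - 1):
                a, b = path[i], path[i + 1]
                used_edges.add((a, b) if a < b else (b, a))
            classes.append(GenomeClass(Permutation(path)))
        if ok:
            out = MaxDistantSet(classes=tuple(classes), n=n, seed=seed)
            out.verify()
            return out
    raise RuntimeError(
        f"failed to construct {k} edge-disjoint Hamiltonian paths of K_{n} "
        f"(seed={seed}); the bound k <= floor(n/2) guarantees existence, so "
        "increase the retry budget"
    )


def nongeodesic_pair(
    n: int, middle: Sequence[int] | Permutation | None = None
) -> tuple[GenomeClass, GenomeClass]:
    """The pair (identity, ``1 2 middle n-1 n``) that no geodesic connects.

    ``middle`` must be a non-identity arrangement of {3, ..., n-2}; with
    ``middle=None`` the adjacent transposition of the first two middle
    labels is used.  Requires n >= 6 so the middle has at least 2 labels.
    """
    if n < 6:
        raise GenomeInputError(f"the non-geodesic family needs n >= 6, got {n}")
    inner = list(range(3, n - 1))
    if middle is None:
        mid = inner.copy()
        mid[0], mid[1] = mid[1], mid[0]
    else:
        mid = [int(v) for v in middle]
    if sorted(mid) != inner:
        raise GenomeInputError(
            f"middle must arrange exactly {{3..{n - 2}}}, got {mid}"
        )
    if mid == inner:
        raise GenomeInputError(
            "identity middle gives the identity genome itself; the family "
            "requires a non-identity arrangement"
        )
    ident = GenomeClass(Permutation(range(1, n + 1)))
    other = GenomeClass(Permutation([1, 2, *mid, n - 1, n]))
    return ident, other
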