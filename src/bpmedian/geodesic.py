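"""Geodesic patches in the breakpoint space of genome classes.

The class space with bp distance is not geodesic: between some pairs x, y
no subset isometric to the full integer segment [0..d(x,y)] exists.  The
weaker object that always exists is the *geodesic patch*, a maximal subset
containing x and y isometric to a subsegment of [0..d(x,y)].  The union of
all patches between x and y, written [x,y]-bar, has a clean combinatorial
characterization:

    z in [x,y]-bar  <=>  d(x,z) + d(z,y) = d(x,y)
                    <=>  A(x) & A(y)  <=  A(z)  <=  A(x) | A(y)

Both criteria are implemented; their equivalence is exercised by the test
suite.  The second one turns enumeration of [x,y]-bar into enumeration of
Hamiltonian paths of the adjacency-union graph that use every common
adjacency, which is what :func:`hamiltonian_paths` provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Optional

from . import _classtable as ct
from .genome_core import (
    ENUMERATION_CAP,
    GenomeClass,
    GenomeInputError,
    GenomeLike,
    Permutation,
    ResourceLimitError,
    adjacency_set,
    bp_distance,
    class_of,
)

__all__ = [
    "GeodesicChain",
    "on_patch",
    "patch_union_set",
    "find_geodesic",
    "hamiltonian_paths",
]


def _check_same_n(*gs: GenomeLike) -> int:
    ns = {class_of(g).n for g in gs}
    if len(ns) != 1:
        raise GenomeInputError(f"mixed genome lengths {sorted(ns)}")
    return ns.pop()


@dataclass(frozen=True)
class GeodesicChain:
    """A geodesic between two classes: classes[i] at distance i from the
    start and |i-j| from classes[j] for every pair (full isometry with the
    discrete segment [0..d])."""

    classes: tuple[GenomeClass, ...]

    @property
    def length(self) -> int:
        return len(self.classes) - 1

    def is_valid(self) -> bool:
        cs = self.classes
        return all(
            bp_distance(cs[i], cs[j]) == j - i
            for i in range(len(cs))
            for j in range(i, len(cs))
        )

    def __iter__(self):
        return iter(self.classes)

    def __len__(self):
        return len(self.classes)


def on_patch(
    z: GenomeLike,
    x: GenomeLike,
    y: GenomeLike,
    criterion: Literal["additivity", "adjacency"] = "additivity",
) -> bool:
    """Whether ``z`` lies on some geodesic patch between ``x`` and ``y``.

    ``criterion="additivity"`` tests d(x,z) + d(z,y) = d(x,y);
    ``criterion="adjacency"`` tests A(x,y) <= A(z) <= A(x) | A(y).
    The two are provably equivalent and both are kept so the equivalence
    can be checked mechanically.
    """
    _check_same_n(z, x, y)
    if criterion == "additivity":
        return bp_distance(x, z) + bp_distance(z, y) == bp_distance(x, y)
    if criterion == "adjacency":
        az = adjacency_set(class_of(z).representative)
        ax = adjacency_set(class_of(x).representative)
        ay = adjacency_set(class_of(y).representative)
        return (ax & ay) <= az <= (ax | ay)
    raise ValueError(f"unknown criterion {criterion!r}")


def patch_union_set(
    x: GenomeLike,
    y: GenomeLike,
    method: Literal["oracle", "hampath"] = "oracle",
    cap: int = ENUMERATION_CAP,
) -> frozenset[GenomeClass]:
    """The set [x,y]-bar of all classes on geodesic patches between x and y.

    ``method="oracle"`` filters the exhaustive class table (n up to the
    enumeration cap); ``method="hampath"`` enumerates Hamiltonian paths of
    the graph A(x) | A(y) through all edges of A(x) & A(y), which scales to
    larger n when the union graph is sparse.  Both return identical sets.
    """
    n = _check_same_n(x, y)
    cx, cy = class_of(x), class_of(y)
    ax, ay = cx.adjacencies(), cy.adjacencies()
    if method == "oracle":
        if n > cap:
            raise ResourceLimitError(
                f"oracle patch enumeration needs n <= {cap}, got n={n}"
            )
        table = ct.class_table(n)
        sel = ct.patch_members_mask(table, ct.mask_of_pairs(ax, n), ct.mask_of_pairs(ay, n))
        return frozenset(table.cls(i) for i in sel.nonzero()[0])
    if method == "hampath":
        return frozenset(
            class_of(p) for p in hamiltonian_paths(n, ax | ay, ax & ay)
        )
    raise ValueError(f"unknown method {method!r}")


def hamiltonian_paths(
    n: int,
    edges: Iterable[tuple[int, int]],
    required: Iterable[tuple[int, int]] = (),
) -> Iterator[Permutation]:
    """Every Hamiltonian path of ({1..n}, edges) using all required edges.

    Yields one permutation per genome class (the canonical orientation),
    with no duplicates; empty when no such path exists.  A depth-first
    search prunes a branch as soon as a required edge can no longer be
    traversed (both endpoints visited without using it).
    """
    edge_set = {(a, b) if a < b else (b, a) for a, b in edges}
    req_set = {(a, b) if a < b else (b, a) for a, b in required}
    if not req_set <= edge_set:
        raise GenomeInputError("required edges must be a subset of edges")
    adj: dict[int, list[int]] = {v: [] for v in range(1, n + 1)}
    req_adj: dict[int, set[int]] = {v: set() for v in range(1, n + 1)}
    for a, b in edge_set:
        adj[a].append(b)
        adj[b].append(a)
    for a, b in req_set:
        req_adj[a].add(b)
        req_adj[b].add(a)
    # a vertex incident to 3+ required edges can use at most 2 of them
    if any(len(s) > 2 for s in req_adj.values()):
        return
    for v in adj:
        adj[v].sort()

    path = [0] * n
    visited = [False] * (n + 1)

    def extend(depth: int, req_used: int) -> Iterator[Permutation]:
        if depth == n:
            if req_used == len(req_set):
                genes = tuple(path)
                if genes <= genes[::-1]:  # one orientation per class
                    yield Permutation(genes)
            return
        u = path[depth - 1]
        for w in adj[u]:
            if visited[w]:
                continue
            # any required edge at w other than {u,w} whose far end is
            # already visited can never be used -> prune
            dead = False
            for r in req_adj[w]:
                if r != u and visited[r]:
                    dead = True
                    break
            if dead:
                continue
            visited[w] = True
            path[depth] = w
            yield from extend(depth + 1, req_used + (w in req_adj[u]))
            visited[w] = False

    for start in range(1, n + 1):
        visited[start] = True
        path[0] = start
        yield from extend(1, 0)
        visited[start] = False


def find_geodesic(
    x: GenomeLike, y: GenomeLike, cap: int = ENUMERATION_CAP
) -> Optional[GeodesicChain]:
    """A geodesic chain from x to y, or None when no geodesic exists.

    Candidates are restricted to [x,y]-bar (every geodesic point satisfies
    the additivity relation) and grouped by distance from x; a depth-first
    search then looks for one class per level with all pairwise distances
    matching |i - j|.  Ties are broken by canonical lexicographic order,
    so the result is deterministic.
    """
    n = _check_same_n(x, y)
    cx, cy = class_of(x), class_of(y)
    d = bp_distance(cx, cy)
    if d == 0:
        return GeodesicChain((cx,))
    if n <= cap:
        members = patch_union_set(cx, cy, method="oracle", cap=cap)
    else:
        members = patch_union_set(cx, cy, method="hampath")
    levels: list[list[GenomeClass]] = [[] for _ in range(d + 1)]
    for z in members:
        levels[bp_distance(cx, z)].append(z)
    if any(not lvl for lvl in levels):
        return None
    for lvl in levels:
        lvl.sort(key=lambda c: c.representative.genes)

    chain: list[GenomeClass] = [cx]

    def extend(i: int) -> bool:
        if i == d + 1:
            return True
        for z in levels[i]:
            if all(bp_distance(chain[j], z) == i - j for j in range(1, i)) and (
                bp_distance(cy, z) == d - i
            ):
                chain.append(z)
                if extend(i + 1):
                    return True
                chain.pop()
        return False

    if extend(1):
        return GeodesicChain(tuple(chain))
    return None
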