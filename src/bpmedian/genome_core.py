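"""Core objects for unsigned linear unichromosomal genomes.

A genome with ``n`` genes is modelled as a permutation of the labels
``1..n``.  Reading a chromosome left-to-right or right-to-left gives the
same molecule, so a genome proper is the *class* ``{pi, reversed(pi)}``;
there are ``n!/2`` such classes for ``n >= 2``.

The breakpoint (bp) distance between two genomes ``x`` and ``y`` is

    d(x, y) = (n - 1) - |A(x) & A(y)|

where ``A(x)`` is the set of *adjacencies* of ``x``: the unordered pairs
of genes that are consecutive in ``x``.  On permutations this is only a
pseudometric (``d(pi, reversed(pi)) = 0``); on classes it is a genuine
metric.  Adjacency sets are represented throughout as frozensets of
``(min, max)`` integer pairs.
"""

from __future__ import annotations

import itertools
from math import factorial
from typing import Iterable, Iterator, Union

__all__ = [
    "GenomeInputError",
    "ResourceLimitError",
    "Permutation",
    "GenomeClass",
    "adjacency_set",
    "all_pairs",
    "common_adjacencies",
    "bp_distance",
    "class_of",
    "enumerate_classes",
    "ENUMERATION_CAP",
]

#: Largest genome length for which exhaustive enumeration of the n!/2
#: classes is permitted (8 -> 20160 classes; enumeration stays sub-second).
ENUMERATION_CAP = 8


class GenomeInputError(ValueError):
    """Raised for malformed genomes: bad labels, mixed lengths, empty sets."""


class ResourceLimitError(RuntimeError):
    """Raised when an exhaustive operation exceeds the enumeration cap."""


def _norm_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


class Permutation:
    """An ordering of the gene labels ``1..n`` (a linear unsigned genome).

    Immutable and hashable.  Two permutations are equal iff their gene
    orders are identical; use :class:`GenomeClass` for orientation-free
    equality.
    """

    __slots__ = ("_genes",)

    def __init__(self, genes: Iterable[int]):
        g = tuple(int(v) for v in genes)
        n = len(g)
        if n < 2:
            raise GenomeInputError(f"genome needs at least 2 genes, got {n}")
        if set(g) != set(range(1, n + 1)):
            raise GenomeInputError(
                f"gene labels must be exactly 1..{n} with no repeats, got {g}"
            )
        self._genes = g

    @classmethod
    def from_string(cls, text: str) -> "Permutation":
        """Parse a whitespace-separated gene order, e.g. ``"1 3 5 2 4 6"``."""
        return cls(int(tok) for tok in text.split())

    @property
    def genes(self) -> tuple[int, ...]:
        return self._genes

    @property
    def n(self) -> int:
        return len(self._genes)

    def reverse(self) -> "Permutation":
        """The same chromosome read in the opposite direction."""
        return Permutation(self._genes[::-1])

    def compose(self, other: "Permutation") -> "Permutation":
        """Function composition ``self o other``: ``(self o other)_i = self[other_i]``."""
        if other.n != self.n:
            raise GenomeInputError("cannot compose permutations of different length")
        s = self._genes
        return Permutation(s[j - 1] for j in other._genes)

    def inverse(self) -> "Permutation":
        """The inverse under composition: ``inverse()[self[i]] = i + 1``."""
        inv = [0] * len(self._genes)
        for i, v in enumerate(self._genes):
            inv[v - 1] = i + 1
        return Permutation(inv)

    def adjacencies(self) -> frozenset[tuple[int, int]]:
        return adjacency_set(self)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes)

    def __getitem__(self, i):
        return self._genes[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Permutation) and self._genes == other._genes

    def __hash__(self) -> int:
        return hash(self._genes)

    def __str__(self) -> str:
        return " ".join(map(str, self._genes))

    def __repr__(self) -> str:
        return f"Permutation({self._genes!r})"


class GenomeClass:
    """The equivalence class ``{pi, reversed(pi)}`` of a permutation.

    The canonical representative is the lexicographically smaller of the
    two orientations, making equality and hashing deterministic.
    """

    __slots__ = ("_rep",)

    def __init__(self, perm: Union[Permutation, Iterable[int]]):
        if not isinstance(perm, Permutation):
            perm = Permutation(perm)
        rev = perm.genes[::-1]
        self._rep = perm if perm.genes <= rev else Permutation(rev)

    @classmethod
    def from_string(cls, text: str) -> "GenomeClass":
        return cls(Permutation.from_string(text))

    @property
    def representative(self) -> Permutation:
        return self._rep

    @property
    def n(self) -> int:
        return self._rep.n

    def members(self) -> tuple[Permutation, Permutation]:
        """Both orientations; identical pair only never occurs for n >= 2."""
        return (self._rep, self._rep.reverse())

    def adjacencies(self) -> frozenset[tuple[int, int]]:
        return adjacency_set(self._rep)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeClass) and self._rep == other._rep

    def __hash__(self) -> int:
        return hash((GenomeClass, self._rep.genes))

    def __str__(self) -> str:
        return str(self._rep)

    def __repr__(self) -> str:
        return f"GenomeClass({self._rep.genes!r})"


GenomeLike = Union[Permutation, GenomeClass]


def _as_perm(g: GenomeLike) -> Permutation:
    if isinstance(g, GenomeClass):
        return g.representative
    if isinstance(g, Permutation):
        return g
    raise GenomeInputError(f"expected Permutation or GenomeClass, got {type(g).__name__}")


def adjacency_set(p: GenomeLike) -> frozenset[tuple[int, int]]:
    """All unordered pairs of consecutive genes of ``p``.

    Invariant under reversal, hence well defined on classes; a genome of
    ``n`` genes has exactly ``n - 1`` adjacencies.
    """
    g = _as_perm(p).genes
    return frozenset(_norm_pair(g[i], g[i + 1]) for i in range(len(g) - 1))


def all_pairs(n: int) -> frozenset[tuple[int, int]]:
    """Every unordered pair of distinct labels from ``1..n`` (edges of K_n)."""
    return frozenset(itertools.combinations(range(1, n + 1), 2))


def common_adjacencies(
    genomes: Iterable[GenomeLike], *, n: int | None = None
) -> frozenset[tuple[int, int]]:
    """Intersection of the adjacency sets of a collection of genomes.

    The empty collection yields *all* pairs of distinct labels, for which
    ``n`` must be supplied (the empty intersection convention).
    """
    perms = [_as_perm(g) for g in genomes]
    if not perms:
        if n is None:
            raise GenomeInputError("empty collection needs an explicit n")
        return all_pairs(n)
    lengths = {p.n for p in perms}
    if len(lengths) != 1:
        raise GenomeInputError(f"mixed genome lengths {sorted(lengths)}")
    if n is not None and n != perms[0].n:
        raise GenomeInputError(f"n={n} does not match genome length {perms[0].n}")
    common = adjacency_set(perms[0])
    for p in perms[1:]:
        common &= adjacency_set(p)
        if not common:
            break
    return common


def bp_distance(x: GenomeLike, y: GenomeLike) -> int:
    """Breakpoint distance ``n - 1 - |A(x) & A(y)|``.

    Symmetric, bounded by ``0 <= d <= n - 1``, satisfies the triangle
    inequality, and is invariant under composition with a fixed
    permutation on either side.  ``d = 0`` iff the two genomes are the
    same class; ``d = n - 1`` iff they share no adjacency.
    """
    px, py = _as_perm(x), _as_perm(y)
    if px.n != py.n:
        raise GenomeInputError(f"mixed genome lengths {px.n} and {py.n}")
    return px.n - 1 - len(adjacency_set(px) & adjacency_set(py))


def class_of(p: GenomeLike) -> GenomeClass:
    """The genome class of ``p``; ``class_of(p) == class_of(reversed(p))``."""
    if isinstance(p, GenomeClass):
        return p
    return GenomeClass(p)


def n_classes(n: int) -> int:
    """Number of genome classes of length ``n``: ``n!/2``."""
    return factorial(n) // 2


def enumerate_classes(n: int, cap: int = ENUMERATION_CAP) -> Iterator[GenomeClass]:
    """Yield every genome class of length ``n`` exactly once.

    Classes are emitted in lexicographic order of their canonical
    representative.  ``n`` above ``cap`` raises :class:`ResourceLimitError`
    (the count n!/2 grows too fast for exhaustive work beyond small n).
    """
    if n < 2:
        raise GenomeInputError(f"need n >= 2, got {n}")
    if n > cap:
        raise ResourceLimitError(
            f"enumerating {factorial(n)//2} classes for n={n} exceeds the cap "
            f"({cap}); raise cap explicitly if you really want this"
        )
    for g in itertools.permutations(range(1, n + 1)):
        if g <= g[::-1]:
            yield GenomeClass(Permutation(g))
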