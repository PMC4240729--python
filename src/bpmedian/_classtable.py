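"""Internal bitmask tables for exhaustive work over all n!/2 genome classes.

Each unordered pair {a, b} of labels (an edge of K_n) gets a bit; the
adjacency set of a genome then becomes a single integer mask, so distance
computations reduce to popcounts and patch-membership tests to two bitwise
comparisons, both vectorisable with numpy over the full class table.
Only valid for n up to the enumeration cap (C(8,2) = 28 bits < 64).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genome_core import (
    ENUMERATION_CAP,
    GenomeClass,
    Permutation,
    ResourceLimitError,
    adjacency_set,
)


@lru_cache(maxsize=None)
def edge_bits(n: int) -> dict[tuple[int, int], int]:
    """Map each normalized pair {a,b}, a<b, to a distinct bit position."""
    return {
        e: i for i, e in enumerate(itertools.combinations(range(1, n + 1), 2))
    }


def mask_of_pairs(pairs, n: int) -> int:
    bits = edge_bits(n)
    m = 0
    for e in pairs:
        m |= 1 << bits[e]
    return m


def mask_of_genes(genes: tuple[int, ...]) -> int:
    n = len(genes)
    bits = edge_bits(n)
    m = 0
    for i in range(n - 1):
        a, b = genes[i], genes[i + 1]
        m |= 1 << bits[(a, b) if a < b else (b, a)]
    return m


@dataclass(frozen=True)
class ClassTable:
    """All genome classes of one length, with adjacency masks.

    ``reps[i]`` is the canonical gene tuple of class ``i`` (lexicographic
    order); ``masks[i]`` its adjacency bitmask; ``index`` the inverse map
    accepting either orientation.
    """

    n: int
    reps: tuple[tuple[int, ...], ...]
    masks: np.ndarray  # uint64, shape (n!/2,)
    index: dict[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.reps)

    def idx(self, g: GenomeClass) -> int:
        return self.index[g.representative.genes]

    def cls(self, i: int) -> GenomeClass:
        return GenomeClass(Permutation(self.reps[i]))

    def mask(self, g: GenomeClass) -> int:
        return int(self.masks[self.idx(g)])


@lru_cache(maxsize=None)
def class_table(n: int) -> ClassTable:
    if not 2 <= n <= ENUMERATION_CAP:
        raise ResourceLimitError(
            f"class table only built for 2 <= n <= {ENUMERATION_CAP}, got n={n}"
        )
    reps = []
    masks = []
    index = {}
    for g in itertools.permutations(range(1, n + 1)):
        if g <= g[::-1]:
            i = len(reps)
            index[g] = i
            index[g[::-1]] = i
            reps.append(g)
            masks.append(mask_of_genes(g))
    return ClassTable(
        n=n,
        reps=tuple(reps),
        masks=np.asarray(masks, dtype=np.uint64),
        index=index,
    )


def popcount(a: np.ndarray) -> np.ndarray:
    return np.bitwise_count(a)


def patch_members_mask(table: ClassTable, mx: int, my: int) -> np.ndarray:
    """Boolean membership in [x,y]-bar over the whole class table.

    z lies on a geodesic patch between x and y iff
    A(x) & A(y) <= A(z) <= A(x) | A(y).
    """
    inter = np.uint64(mx & my)
    union = np.uint64(mx | my)
    M = table.masks
    return ((M & inter) == inter) & ((M | union) == union)
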