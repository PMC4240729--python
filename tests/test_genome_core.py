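"""Permutations, classes, adjacency sets, and the bp pseudometric."""

import itertools
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpmedian import (
    GenomeClass,
    GenomeInputError,
    Permutation,
    ResourceLimitError,
    adjacency_set,
    all_pairs,
    bp_distance,
    class_of,
    common_adjacencies,
    enumerate_classes,
    n_classes,
)

from conftest import random_perm

perms = st.integers(2, 7).flatmap(
    lambda n: st.permutations(list(range(1, n + 1))).map(Permutation)
)


class TestPermutation:
    @pytest.mark.parametrize(
        "genes", [[1, 1, 2], [0, 1, 2], [2, 3, 4], [1], [], [1, 2, 4]]
    )
    def test_invalid_labels_rejected(self, genes):
        with pytest.raises(GenomeInputError):
            Permutation(genes)

    def test_parsing_and_roundtrip(self):
        p = Permutation.from_string("1 3 5 2 4 6")
        assert p.genes == (1, 3, 5, 2, 4, 6)
        assert Permutation.from_string(str(p)) == p

    def test_reverse_is_involution(self):
        p = Permutation([3, 1, 2, 4])
        assert p.reverse().reverse() == p
        assert p.reverse().genes == (4, 2, 1, 3)


class TestAdjacencySet:
    def test_identity(self):
        assert adjacency_set(Permutation([1, 2, 3, 4])) == {(1, 2), (2, 3), (3, 4)}

    def test_reversal_invariance(self):
        assert adjacency_set(Permutation([4, 3, 2, 1])) == adjacency_set(
            Permutation([1, 2, 3, 4])
        )

    def test_hand_computed_example(self):
        got = adjacency_set(Permutation([1, 3, 5, 2, 4, 6]))
        assert got == {(1, 3), (3, 5), (2, 5), (2, 4), (4, 6)}

    @given(perms)
    @settings(max_examples=50, derandomize=True)
    def test_size_is_n_minus_1(self, p):
        assert len(adjacency_set(p)) == p.n - 1


class TestCommonAdjacencies:
    def test_singleton(self):
        p = Permutation([1, 2, 3, 4])
        assert common_adjacencies([p]) == adjacency_set(p)

    def test_maximally_distant_pair_shares_nothing(self):
        x = Permutation([1, 2, 3, 4, 5, 6])
        y = Permutation([1, 3, 5, 2, 4, 6])
        assert common_adjacencies([x, y]) == frozenset()

    def test_partial_overlap(self):
        got = common_adjacencies([Permutation([1, 2, 3, 4]), Permutation([2, 1, 4, 3])])
        assert got == {(1, 2), (3, 4)}

    def test_empty_collection_is_all_pairs(self):
        assert common_adjacencies([], n=4) == all_pairs(4)
        assert len(all_pairs(5)) == 10
        with pytest.raises(GenomeInputError):
            common_adjacencies([])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(GenomeInputError):
            common_adjacencies([Permutation([1, 2, 3]), Permutation([1, 2, 3, 4])])

    def test_intersection_of_unions(self, rng):
        # A over a union of genome sets = intersection of the A's
        for _ in range(20):
            I = [random_perm(6, rng) for _ in range(2)]
            J = [random_perm(6, rng) for _ in range(3)]
            assert common_adjacencies(I + J) == common_adjacencies(
                I
            ) & common_adjacencies(J)


class TestBpDistance:
    def test_worked_maximum(self):
        x = Permutation([1, 2, 3, 4, 5, 6])
        y = Permutation([1, 3, 5, 2, 4, 6])
        assert bp_distance(x, y) == 5

    def test_reversal_at_distance_zero(self, rng):
        for _ in range(10):
            p = random_perm(7, rng)
            assert bp_distance(p, p.reverse()) == 0

    def test_hand_computed(self):
        assert bp_distance(Permutation([1, 2, 3, 4]), Permutation([2, 1, 4, 3])) == 1

    def test_mixed_lengths_rejected(self):
        with pytest.raises(GenomeInputError):
            bp_distance(Permutation([1, 2, 3]), Permutation([1, 2, 3, 4]))

    def test_pseudometric_axioms_exhaustive_n4(self):
        ps = [Permutation(g) for g in itertools.permutations(range(1, 5))]
        for x in ps:
            assert bp_distance(x, x) == 0
        for x, y in itertools.combinations(ps, 2):
            assert bp_distance(x, y) == bp_distance(y, x)
            assert 0 <= bp_distance(x, y) <= 3
        for x, y, z in itertools.product(ps, repeat=3):
            assert bp_distance(x, z) <= bp_distance(x, y) + bp_distance(y, z)

    def test_pseudometric_axioms_randomized(self, rng):
        for n in (6, 8):
            for _ in range(2500):
                x, y, z = (random_perm(n, rng) for _ in range(3))
                dxy, dyz, dxz = bp_distance(x, y), bp_distance(y, z), bp_distance(x, z)
                assert dxy == bp_distance(y, x)
                assert 0 <= dxy <= n - 1
                assert dxz <= dxy + dyz

    def test_metric_on_classes_exhaustive_n4(self):
        cs = list(enumerate_classes(4))
        for a, b in itertools.product(cs, repeat=2):
            assert (bp_distance(a, b) == 0) == (a == b)

    def test_invariance_under_relabeling(self, rng):
        # with (x o z)_i = x_{z_i}, left composition relabels gene values
        # through z, mapping both adjacency sets by the same bijection, so
        # d(zx, zy) = d(x, y); hence d(x, y) = d(id, x^{-1}y).  (The
        # position-shuffling side x -> xz does not preserve the distance.)
        idp = Permutation(range(1, 8))
        for _ in range(200):
            x, y, z = (random_perm(7, rng) for _ in range(3))
            d = bp_distance(x, y)
            assert bp_distance(z.compose(x), z.compose(y)) == d
            assert bp_distance(idp, x.inverse().compose(y)) == d

    def test_max_distance_iff_no_common_adjacency(self, rng):
        for _ in range(100):
            x, y = random_perm(6, rng), random_perm(6, rng)
            assert (bp_distance(x, y) == 5) == (not common_adjacencies([x, y]))


class TestClasses:
    def test_canonical_representative(self):
        assert class_of(Permutation([4, 3, 2, 1])).representative.genes == (1, 2, 3, 4)

    @given(perms)
    @settings(max_examples=50, derandomize=True)
    def test_class_of_reversal(self, p):
        assert class_of(p) == class_of(p.reverse())

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_class_counts(self, n):
        cs = list(enumerate_classes(n))
        assert len(cs) == n_classes(n) == factorial(n) // 2
        assert len(set(cs)) == len(cs)

    def test_exhaustive_class_identification_n4(self):
        reps = {class_of(Permutation(g)) for g in itertools.permutations(range(1, 5))}
        assert len(reps) == 12

    def test_enumeration_cap(self):
        with pytest.raises(ResourceLimitError):
            list(enumerate_classes(9))
        with pytest.raises(GenomeInputError):
            list(enumerate_classes(1))

    def test_class_hash_and_equality(self):
        a = GenomeClass(Permutation([1, 3, 2, 4]))
        b = GenomeClass(Permutation([4, 2, 3, 1]))
        assert a == b and hash(a) == hash(b)
        assert len({a, b}) == 1
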