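"""Total distance, exact medians, accessibility closures."""

import itertools

import pytest

from bpmedian import (
    GenomeClass,
    GenomeInputError,
    Permutation,
    WeightedGenomeSet,
    accessible_closure,
    bp_distance,
    class_of,
    conjecture1_report,
    is_median_maxdist,
    max_distant_set,
    median_bruteforce,
    median_set_maxdist,
    one_step_accessible,
    patch_union_set,
    total_distance,
)

from conftest import random_perm


class TestWeightedGenomeSet:
    def test_class_collapsing_sums_weights(self):
        p = Permutation([1, 3, 2, 4])
        A = WeightedGenomeSet([p, p.reverse(), Permutation([1, 2, 3, 4])], [2, 3, 1])
        assert len(A) == 2
        assert A.multiplicity(p) == 5

    def test_empty_rejected(self):
        with pytest.raises(GenomeInputError):
            WeightedGenomeSet([])

    def test_bad_weights_rejected(self):
        with pytest.raises(GenomeInputError):
            WeightedGenomeSet([Permutation([1, 2, 3])], [0])

    def test_equivalent_inputs_give_equal_sets(self, rng):
        ps = [random_perm(6, rng) for _ in range(4)]
        flipped = [p.reverse() if i % 2 else p for i, p in enumerate(ps)]
        assert WeightedGenomeSet(ps) == WeightedGenomeSet(flipped)


class TestTotalDistance:
    def test_member_of_singleton(self):
        p = Permutation([2, 1, 3, 4])
        assert total_distance(p, WeightedGenomeSet([p])) == 0

    def test_input_point_of_maxdist_triple(self):
        mds = max_distant_set(7, 3, seed=11)
        A = WeightedGenomeSet(list(mds))
        assert total_distance(mds.classes[0], A) == 2 * 6

    def test_weight_linearity(self, rng):
        q = random_perm(6, rng)
        members = [random_perm(6, rng) for _ in range(3)]
        base = total_distance(q, WeightedGenomeSet(members))
        doubled = total_distance(q, WeightedGenomeSet(members, [2, 1, 1]))
        assert doubled == base + bp_distance(q, members[0])

    def test_invariant_under_reversal_of_query_and_members(self, rng):
        q = random_perm(6, rng)
        members = [random_perm(6, rng) for _ in range(3)]
        A = WeightedGenomeSet(members)
        A_flip = WeightedGenomeSet([m.reverse() for m in members])
        assert total_distance(q, A) == total_distance(q.reverse(), A_flip)


class TestMedianBruteforce:
    def test_singleton(self):
        p = class_of(Permutation([3, 1, 2, 4]))
        res = median_bruteforce(WeightedGenomeSet([p]))
        assert res.value == 0 and res.medians == {p}

    def test_two_point_median_is_patch_union(self, rng):
        for _ in range(5):
            x, y = random_perm(5, rng), random_perm(5, rng)
            res = median_bruteforce(WeightedGenomeSet([x, y]))
            assert res.value == bp_distance(x, y)
            assert res.medians == patch_union_set(x, y)

    @pytest.mark.parametrize("n,k", [(4, 2), (5, 2), (6, 2), (6, 3), (7, 2), (7, 3)])
    def test_maxdist_value_formula(self, n, k):
        mds = max_distant_set(n, k, seed=n * 10 + k)
        res = median_bruteforce(WeightedGenomeSet(list(mds)))
        assert res.value == (k - 1) * (n - 1)

    def test_value_invariant_under_reversals(self, rng):
        members = [random_perm(6, rng) for _ in range(3)]
        res = median_bruteforce(WeightedGenomeSet(members))
        flipped = median_bruteforce(
            WeightedGenomeSet([m.reverse() for m in members])
        )
        assert res.value == flipped.value and res.medians == flipped.medians


class TestMaxdistMedianSet:
    @pytest.mark.parametrize("n,k", [(5, 2), (6, 3), (7, 2), (7, 3)])
    def test_agrees_with_bruteforce(self, n, k):
        mds = max_distant_set(n, k, seed=n + k)
        exact = median_bruteforce(WeightedGenomeSet(list(mds)))
        fast = median_set_maxdist(list(mds))
        assert fast.value == exact.value == (k - 1) * (n - 1)
        assert fast.medians == exact.medians

    def test_inputs_are_medians(self):
        mds = max_distant_set(7, 3, seed=3)
        res = median_set_maxdist(list(mds))
        assert set(mds.classes) <= res.medians
        for x in mds:
            assert is_median_maxdist(x, list(mds))

    def test_membership_test_agrees_with_bruteforce(self):
        mds = max_distant_set(6, 2, seed=9)
        exact = median_bruteforce(WeightedGenomeSet(list(mds))).medians
        from bpmedian import enumerate_classes

        for z in enumerate_classes(6):
            assert is_median_maxdist(z, list(mds)) == (z in exact)

    def test_precondition_enforced(self):
        close = [Permutation([1, 2, 3, 4, 5]), Permutation([1, 2, 3, 5, 4])]
        with pytest.raises(GenomeInputError):
            median_set_maxdist(close)
        with pytest.raises(GenomeInputError):
            is_median_maxdist(Permutation([1, 2, 3, 4, 5]), close)

    def test_adjacency_outside_union_breaks_median(self):
        # swap two genes of an input to create an adjacency not in the union
        mds = max_distant_set(7, 3, seed=21)
        union = frozenset()
        for x in mds:
            union |= x.adjacencies()
        found = None
        for g in itertools.permutations(range(1, 8)):
            cand = GenomeClass(Permutation(g))
            extra = cand.adjacencies() - union
            if len(extra) == 1:
                found = cand
                break
        assert found is not None
        assert not is_median_maxdist(found, list(mds))
        A = WeightedGenomeSet(list(mds))
        assert total_distance(found, A) > 2 * 6


class TestAccessibility:
    def test_singleton_is_fixed(self, id6):
        assert one_step_accessible([id6]) == {id6}
        assert accessible_closure([id6]) == {id6}

    def test_contains_seed_and_pairwise_patches(self):
        mds = max_distant_set(7, 3, seed=2)
        X = list(mds)
        z1 = one_step_accessible(X)
        assert set(X) <= z1
        for x, y in itertools.combinations(X, 2):
            assert patch_union_set(x, y) <= z1

    def test_one_step_within_closure(self):
        mds = max_distant_set(6, 3, seed=4)
        z1 = one_step_accessible(list(mds))
        zbar = accessible_closure(list(mds))
        assert z1 <= zbar

    def test_closure_is_fixed_point(self):
        mds = max_distant_set(6, 2, seed=8)
        zbar = accessible_closure(list(mds))
        assert one_step_accessible(zbar) == zbar

    def test_closure_within_median_set_maxdist(self):
        mds = max_distant_set(7, 3, seed=6)
        zbar = accessible_closure(list(mds))
        res = median_bruteforce(WeightedGenomeSet(list(mds)))
        assert zbar <= res.medians

    def test_random_inputs_closure_contains_patches(self, rng):
        X = [random_perm(5, rng) for _ in range(3)]
        zbar = accessible_closure(X)
        for x, y in itertools.combinations(X, 2):
            assert patch_union_set(x, y) <= zbar


class TestConjectureReport:
    def test_two_point_case_equality(self):
        mds = max_distant_set(6, 2, seed=14)
        rep = conjecture1_report(list(mds))
        # the median set of a pair is the patch union, which is reachable
        # in one hop: the conjecture holds trivially here
        assert rep.equal
        assert rep.medians == patch_union_set(*mds.classes)

    def test_report_contents(self):
        mds = max_distant_set(7, 3, seed=1)
        rep = conjecture1_report(list(mds))
        assert rep.n == 7 and rep.k == 3
        assert rep.median_value == 12
        assert rep.accessible <= rep.medians
        assert rep.missing == rep.medians - rep.accessible
        s = rep.summary()
        assert s["n_medians"] == len(rep.medians)
        assert s["n_missing"] == len(rep.missing)

    def test_requires_maxdist(self, rng):
        with pytest.raises(GenomeInputError):
            conjecture1_report([Permutation([1, 2, 3, 4]), Permutation([1, 2, 4, 3])])
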