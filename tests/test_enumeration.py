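"""Viable subclone tree enumeration: worked examples, invariants, oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subclonetk.clustering import ClusterSet
from subclonetk.enumeration import (
    SubcloneTree,
    enumerate_structures,
    evaluate_tree,
    implied_cp,
    mutation_profile,
    normal_fraction,
)


def brute_force_viable(cps, tol=1e-9):
    """Independent oracle: evaluate ALL rooted labeled trees on
    {root, 1..n} — including CP-order-violating ones — by the SF rule
    and return the canonical forms of the viable ones.

    Trees are enumerated as parent functions (each non-root node picks
    any other node), keeping only acyclic ones; there are (n+1)^(n-1)
    such trees.
    """
    n = len(cps)
    viable = set()
    count_trees = 0
    for parents in itertools.product(range(n + 1), repeat=n):
        # reject self-parenting and cycles
        if any(parents[k - 1] == k for k in range(1, n + 1)):
            continue
        ok = True
        for k in range(1, n + 1):
            seen = {k}
            v = k
            while v != 0:
                v = parents[v - 1]
                if v in seen:
                    ok = False
                    break
                seen.add(v)
            if not ok:
                break
        if not ok:
            continue
        count_trees += 1
        c = [1.0, *cps]
        sf = list(c)
        for k in range(1, n + 1):
            sf[parents[k - 1]] -= c[k]
        if min(sf) < -tol:
            continue

        def canon(v):
            kids = tuple(
                canon(u) for u in range(1, n + 1) if parents[u - 1] == v
            )
            return (f"C{v}" if v else "", kids)

        viable.add(canon(0))
    assert count_trees == (n + 1) ** (n - 1)
    return viable


def make_set(cps):
    labels = tuple(f"C{k}" for k in range(1, len(cps) + 1))
    return ClusterSet("s", labels, tuple(cps))


class TestWorkedExamples:
    def test_two_clusters_chain_and_branch(self, two_cluster_set):
        sols = enumerate_structures(two_cluster_set)
        assert sols.visited == 2 and sols.viable == 2
        assert [t.parents for t in sols.trees] == [(0, 1), (0, 0)]  # chain first
        chain, branch = sols.trees
        assert chain.sf == pytest.approx((0.4, 0.3, 0.3))
        assert branch.sf == pytest.approx((0.1, 0.6, 0.3))

    def test_two_clusters_chain_only(self, chain_only_set):
        sols = enumerate_structures(chain_only_set)
        assert sols.visited == 2 and sols.viable == 1
        assert sols.trees[0].parents == (0, 1)

    def test_three_clusters(self, three_cluster_set):
        sols = enumerate_structures(three_cluster_set)
        assert sols.visited == 6 and sols.viable == 2
        assert {t.parents for t in sols.trees} == {(0, 1, 2), (0, 1, 1)}

    def test_branch_rejection_by_evaluation(self):
        assert evaluate_tree((0, 0), (0.8, 0.5)) is None
        assert evaluate_tree((0, 1), (0.8, 0.5)) == pytest.approx((0.2, 0.3, 0.5))

    def test_purity_one_boundary(self):
        sf = evaluate_tree((0,), (1.0,))
        assert sf == pytest.approx((0.0, 1.0))

    def test_normal_fraction(self, two_cluster_set):
        sols = enumerate_structures(two_cluster_set)
        assert normal_fraction(sols.trees[0]) == pytest.approx(0.4)
        assert normal_fraction(sols.trees[1]) == pytest.approx(0.1)


class TestProfilesAndImpliedCP:
    def test_mutation_profiles(self, two_cluster_solutions):
        chain, branch = two_cluster_solutions.trees
        assert mutation_profile(chain, 2) == {"A", "B"}
        assert mutation_profile(chain, 0) == frozenset()
        assert mutation_profile(branch, 2) == {"B"}
        with pytest.raises(KeyError):
            mutation_profile(chain, 7)

    def test_implied_cp_reproduces_input(self, two_cluster_solutions):
        for tree in two_cluster_solutions.trees:
            assert implied_cp(tree) == pytest.approx((0.6, 0.3), abs=1e-9)

    def test_implied_cp_random_sweep(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            cps = tuple(sorted(rng.uniform(0.02, 1.0, n), reverse=True))
            if len(set(cps)) < n:
                continue
            for tree in enumerate_structures(make_set(cps)).trees:
                assert implied_cp(tree) == pytest.approx(cps, abs=1e-9)
                assert sum(tree.sf) == pytest.approx(1.0, abs=1e-9)


class TestInvariants:
    def test_chain_always_viable_and_first(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(1, 7))
            cps = np.sort(rng.uniform(0.01, 1.0, n))[::-1]
            if len(set(cps)) < n:
                continue
            sols = enumerate_structures(make_set(tuple(cps)))
            assert sols.viable >= 1
            assert sols.trees[0].parents == tuple(range(n))
            assert sols.viable <= math.factorial(n)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_scaling_cps_down_grows_viable_set(self, seed):
        rng = np.random.default_rng(seed)
        n = 4
        cps = np.sort(rng.uniform(0.05, 1.0, n))[::-1]
        if len(set(cps)) < n:
            return
        lam = rng.uniform(0.2, 1.0)
        before = {t.parents for t in enumerate_structures(make_set(tuple(cps))).trees}
        after = {
            t.parents
            for t in enumerate_structures(make_set(tuple(cps * lam))).trees
        }
        assert before <= after

    def test_duplicate_cps_rejected(self):
        with pytest.raises(ValueError):
            make_set((0.5, 0.5))

    def test_empty_cluster_set_gives_normal_only_tree(self):
        sols = enumerate_structures(ClusterSet("s", (), ()))
        assert sols.viable == 1
        assert sols.trees[0].sf == (1.0,)
        assert normal_fraction(sols.trees[0]) == 1.0

    def test_max_n_guard(self):
        cps = tuple(np.linspace(0.9, 0.1, 11))
        with pytest.raises(ValueError):
            enumerate_structures(make_set(cps))


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_brute_force_over_all_labeled_trees(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            cps = tuple(np.sort(rng.uniform(0.02, 1.0, n))[::-1])
            if len(set(cps)) < n:
                continue
            fast = {t.canonical() for t in enumerate_structures(make_set(cps)).trees}
            assert fast == brute_force_viable(cps)


class TestSerialization:
    def test_dict_round_trip(self, two_cluster_solutions):
        for tree in two_cluster_solutions.trees:
            assert SubcloneTree.from_dict(tree.to_dict()) == tree

    def test_newick_chain_depth(self):
        cps = (0.8, 0.6, 0.4)
        sols = enumerate_structures(make_set(cps))
        chain = sols.trees[0]
        nwk = chain.to_newick()
        assert nwk.count("(") == 3 and nwk.endswith(";")
        assert "C3" in nwk and "normal" in nwk
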