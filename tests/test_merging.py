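"""Cross-sample compatibility, grafting and solution-set trimming."""

import pytest

from subclonetk.clustering import ClusterSet
from subclonetk.enumeration import SolutionSet, SubcloneTree, enumerate_structures
from subclonetk.merging import (
    MergeError,
    is_compatible,
    merge_trees,
    shared_clusters,
    trim_solution_sets,
)


def tree(labels, cps, parents):
    from subclonetk.enumeration import evaluate_tree

    sf = evaluate_tree(parents, cps)
    assert sf is not None
    return SubcloneTree(tuple(labels), tuple(cps), tuple(parents), sf)


def test_shared_clusters():
    p = ClusterSet("p", ("A", "B"), (0.9, 0.6))
    r = ClusterSet("r", ("A", "C"), (0.9, 0.5))
    assert shared_clusters(p, r) == {"A"}
    assert shared_clusters(p, p) == {"A", "B"}
    assert shared_clusters(p, ClusterSet("r", ("D",), (0.4,))) == set()


class TestCompatibility:
    def test_compatible_chains(self):
        p = tree(("A", "B"), (0.9, 0.6), (0, 1))  # root->A->B
        r = tree(("A", "C"), (0.9, 0.5), (0, 1))  # root->A->C
        ok, anchors = is_compatible(p, r, {"A", "B"})
        assert ok
        assert anchors == {0: 0, 1: 1, 2: 1}  # C extends A's node

    def test_incompatible_profile(self):
        # P: root->A->B ; R contains a node whose shared profile is {B}
        # but B never occurs without A in the primary
        p = tree(("A", "B"), (0.9, 0.6), (0, 1))
        r = tree(("B", "C"), (0.7, 0.5), (0, 1))
        ok, anchors = is_compatible(p, r, {"A", "B"})
        assert not ok and anchors is None

    def test_vacuous_when_no_shared(self):
        p = tree(("A", "B"), (0.9, 0.6), (0, 1))
        r = tree(("C",), (0.5,), (0,))
        ok, anchors = is_compatible(p, r, set())
        assert ok
        assert set(anchors.values()) == {0}


class TestMergeTrees:
    def test_graft_extension_at_anchor(self):
        p = tree(("A", "B"), (0.9, 0.6), (0, 1))
        r = tree(("A", "C"), (0.9, 0.5), (0, 1))
        shared = {"A", "B"}
        ok, anchors = is_compatible(p, r, shared)
        merged = merge_trees(p, r, anchors, shared)
        profs = set(merged.profiles)
        assert profs == {
            frozenset(),
            frozenset({"A"}),
            frozenset({"A", "B"}),
            frozenset({"A", "C"}),
        }
        # C's node is a child of A's node
        c_node = merged.profiles.index(frozenset({"A", "C"}))
        a_node = merged.profiles.index(frozenset({"A"}))
        assert merged.parents[c_node] == a_node
        merged.validate()

    def test_identical_trees_merge_to_primary(self):
        p = tree(("A", "B"), (0.9, 0.6), (0, 1))
        shared = {"A", "B"}
        ok, anchors = is_compatible(p, p, shared)
        merged = merge_trees(p, p, anchors, shared)
        assert merged.n_nodes == 3
        assert set(merged.profiles) == {
            frozenset(),
            frozenset({"A"}),
            frozenset({"A", "B"}),
        }

    def test_novel_chain_grafted_at_root(self):
        p = tree(("A",), (0.9,), (0,))
        r = tree(("X", "Y"), (0.6, 0.3), (0, 1))
        ok, anchors = is_compatible(p, r, set())
        merged = merge_trees(p, r, anchors, set())
        x = merged.profiles.index(frozenset({"X"}))
        y = merged.profiles.index(frozenset({"X", "Y"}))
        assert merged.parents[x] == 0
        assert merged.parents[y] == x
        merged.validate()

    def test_merge_conditions_hold_by_construction(self):
        p_sols = enumerate_structures(ClusterSet("p", ("A", "B"), (0.8, 0.4)))
        r_sols = enumerate_structures(ClusterSet("r", ("A", "C"), (0.9, 0.7)))
        shared = {"A"}
        for pt in p_sols.trees:
            for rt in r_sols.trees:
                ok, anchors = is_compatible(pt, rt, shared)
                if ok:
                    merge_trees(pt, rt, anchors, shared).validate()

    def test_ordering_anomaly_detected(self):
        """A shared cluster acquired after a relapse-only cluster, while
        the primary carries it independently, implies the same mutation
        arising twice; the graft is rejected."""
        p = tree(("A",), (0.9,), (0,))  # A exists alone in primary
        r = tree(("X", "A"), (0.6, 0.3), (0, 1))  # relapse: A arises under X
        shared = {"A"}
        ok, anchors = is_compatible(p, r, shared)
        assert ok  # profile test alone cannot see the anomaly
        with pytest.raises(MergeError):
            merge_trees(p, r, anchors, shared)


class TestTrim:
    def test_trim_to_unique_pair(self):
        # relapse pins the primary: single dominant relapse clone carrying A+B
        p_sols = enumerate_structures(ClusterSet("p", ("A", "B"), (0.6, 0.3)))
        assert p_sols.viable == 2
        r_sols = enumerate_structures(ClusterSet("r", ("A", "B"), (0.9, 0.85)))
        assert r_sols.viable == 1  # the chain only
        tp, tr, merged = trim_solution_sets(p_sols, r_sols)
        assert tp.viable == 1 and tp.trees[0].parents == (0, 1)
        assert tr.viable == 1
        assert len(merged) == 1

    def test_both_relapse_structures_compatible(self):
        # relapse-specific cluster C can sit under A or beside it; both
        # relapse structures extend the sole primary structure
        p_sols = enumerate_structures(ClusterSet("p", ("A",), (0.8,)))
        r_sols = enumerate_structures(ClusterSet("r", ("A", "C"), (0.6, 0.3)))
        assert p_sols.viable == 1 and r_sols.viable == 2
        tp, tr, merged = trim_solution_sets(p_sols, r_sols)
        assert tp.viable == 1 and tr.viable == 2 and len(merged) == 2

    def test_trim_is_idempotent(self):
        p_sols = enumerate_structures(ClusterSet("p", ("A", "B"), (0.6, 0.3)))
        r_sols = enumerate_structures(ClusterSet("r", ("A", "C"), (0.9, 0.5)))
        tp1, tr1, m1 = trim_solution_sets(p_sols, r_sols)
        tp2, tr2, m2 = trim_solution_sets(tp1, tr1)
        assert [t.parents for t in tp1.trees] == [t.parents for t in tp2.trees]
        assert [t.parents for t in tr1.trees] == [t.parents for t in tr2.trees]
        assert len(m1) == len(m2)

    def test_zero_pairs_warns_and_empties(self):
        # A and B swap order between samples: no tree survives in either
        p_sols = enumerate_structures(ClusterSet("p", ("A", "B"), (0.9, 0.85)))
        r_sols = enumerate_structures(ClusterSet("r", ("B", "A"), (0.9, 0.85)))
        # both single chains, mutually incompatible (A under B vs B under A)
        with pytest.warns(UserWarning):
            tp, tr, merged = trim_solution_sets(p_sols, r_sols)
        assert tp.viable == 0 and tr.viable == 0 and merged == []

    def test_requires_nonempty_sets(self):
        sols = enumerate_structures(ClusterSet("p", ("A",), (0.5,)))
        empty = SolutionSet("r", ClusterSet("r", ("A",), (0.5,)), [], 1)
        with pytest.raises(ValueError):
            trim_solution_sets(sols, empty)
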