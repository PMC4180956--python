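"""Exhaustive enumeration of viable subclone evolutionary trees.

Given one sample's clusters with strictly descending CP values
``cp_1 > cp_2 > ... > cp_n``, every candidate evolutionary history is a
rooted tree in which the root is the mutation-free normal ("null")
subclone and each cluster founds one subclone.  A cluster can only
arise inside a subclone whose own cluster has a CP at least as large,
so the cluster of rank k may attach to the root or to any cluster of
rank < k — k choices — giving exactly n! candidate topologies.

Each candidate is evaluated by assigning subclone frequencies (SF)
bottom-up:

    SF(v) = CP(v) - sum of CP over v's children,   CP(root) := 1

(the telescoped form of "CP minus the sum of the SFs of all
descendants").  A tree is viable when no SF is negative beyond
tolerance; the root SF is the normal-tissue contamination.  The linear
mutation-accumulation chain (rank k under rank k-1) is always viable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .clustering import ClusterSet

__all__ = [
    "SubcloneTree",
    "SolutionSet",
    "enumerate_structures",
    "evaluate_tree",
    "implied_cp",
    "mutation_profile",
    "normal_fraction",
    "viable_parent_vectors",
]

DEFAULT_SF_TOLERANCE = 1e-9
DEFAULT_MAX_N = 10
_CHUNK = 200_000


@dataclass(frozen=True)
class SubcloneTree:
    """A rooted subclone tree over ranked clusters.

    Node 0 is the normal root; node k (1-based) hosts the cluster of
    rank k (k-th largest CP).  ``parents[k-1]`` is the parent node of
    node k; ``sf`` holds the n+1 subclone frequencies, root first.
    """

    labels: Tuple[str, ...]
    cps: Tuple[float, ...]
    parents: Tuple[int, ...]
    sf: Tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    def children(self, node: int) -> List[int]:
        """Children of ``node``, ordered by cluster CP descending."""
        return [k for k in range(1, self.n + 1) if self.parents[k - 1] == node]

    def node_cp(self, node: int) -> float:
        return 1.0 if node == 0 else self.cps[node - 1]

    def node_profile(self, node: int) -> FrozenSet[str]:
        """Cumulative mutation profile: cluster labels on the root path."""
        if not (0 <= node <= self.n):
            raise KeyError(f"no node {node} in tree with {self.n} clusters")
        out = set()
        while node != 0:
            out.add(self.labels[node - 1])
            node = self.parents[node - 1]
        return frozenset(out)

    def node_profiles(self) -> List[FrozenSet[str]]:
        return [self.node_profile(v) for v in range(self.n + 1)]

    def ancestors(self, node: int) -> List[int]:
        out = []
        while node != 0:
            node = self.parents[node - 1]
            out.append(node)
        return out

    @property
    def normal_fraction(self) -> float:
        return self.sf[0]

    def implied_cp(self) -> Tuple[float, ...]:
        """CP of each cluster implied by the SFs: subtree SF sums."""
        acc = list(self.sf)
        for k in range(self.n, 0, -1):  # children always have larger rank
            acc[self.parents[k - 1]] += acc[k]
        return tuple(acc[1:])

    def canonical(self):
        """Nested-tuple canonical form (labels with children sorted by CP)."""

        def rec(v: int):
            kids = tuple(rec(c) for c in self.children(v))
            return (self.labels[v - 1] if v else "", kids)

        return rec(0)

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {"label": l, "cp": cp} for l, cp in zip(self.labels, self.cps)
            ],
            "nodes": [
                {
                    "id": v,
                    "cluster": self.labels[v - 1] if v else None,
                    "sf": self.sf[v],
                    "children": self.children(v),
                }
                for v in range(self.n + 1)
            ],
            "normal_fraction": self.normal_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubcloneTree":
        labels = tuple(c["label"] for c in d["clusters"])
        cps = tuple(float(c["cp"]) for c in d["clusters"])
        parents = [0] * len(labels)
        for node in d["nodes"]:
            for child in node["children"]:
                parents[child - 1] = node["id"]
        sf = tuple(float(node["sf"]) for node in sorted(d["nodes"], key=lambda x: x["id"]))
        return cls(labels, cps, tuple(parents), sf)

    def to_newick(self) -> str:
        """Newick string; node names are cluster labels, branch lengths SFs."""

        def rec(v: int) -> str:
            kids = self.children(v)
            name = self.labels[v - 1] if v else "normal"
            inner = f"({','.join(rec(c) for c in kids)})" if kids else ""
            return f"{inner}{name}:{self.sf[v]:.6g}"

        return rec(0) + ";"


@dataclass
class SolutionSet:
    """All viable subclone trees for one sample's cluster CP vector."""

    sample_id: str
    cluster_set: ClusterSet
    trees: List[SubcloneTree]
    visited: int

    @property
    def viable(self) -> int:
        return len(self.trees)


def _parent_ranges(n: int):
    # descending per-position choices => the linear chain (0,1,...,n-1) first
    return (range(k - 1, -1, -1) for k in range(1, n + 1))


@lru_cache(maxsize=8)
def _parent_matrix(n: int) -> np.ndarray:
    return np.fromiter(
        itertools.chain.from_iterable(itertools.product(*_parent_ranges(n))),
        dtype=np.int64,
    ).reshape(-1, n)


def _iter_parent_chunks(n: int):
    if n <= 8:
        yield _parent_matrix(n)
        return
    it = itertools.product(*_parent_ranges(n))
    while True:
        block = list(itertools.islice(it, _CHUNK))
        if not block:
            return
        yield np.asarray(block, dtype=np.int64)


def evaluate_tree(
    parents: Sequence[int],
    cps: Sequence[float],
    sf_tolerance: float = DEFAULT_SF_TOLERANCE,
) -> Optional[Tuple[float, ...]]:
    """Assign subclone frequencies to a topology; None if not viable.

    Post-order SF assignment reduces to SF(v) = CP(v) - sum(CP(children));
    any SF below ``-sf_tolerance`` makes the structure biologically
    implausible (a subclone cannot have negative mass) and it is
    rejected.  Surviving SFs are clamped into [0, 1].
    """
    c = [1.0, *cps]
    sf = list(c)
    for k, p in enumerate(parents, 1):
        sf[p] -= c[k]
    if min(sf) < -sf_tolerance:
        return None
    return tuple(min(1.0, max(0.0, v)) for v in sf)


def viable_parent_vectors(
    cps: Sequence[float], sf_tolerance: float = DEFAULT_SF_TOLERANCE
) -> List[Tuple[int, ...]]:
    """All CP-order-respecting parent vectors with non-negative SFs.

    Vectorized over the full n! candidate set; candidates are visited in
    an order that puts the linear accumulation chain first.
    """
    n = len(cps)
    if n == 0:
        return [()]
    c = np.concatenate(([1.0], np.asarray(cps, dtype=float)))
    out: List[Tuple[int, ...]] = []
    for P in _iter_parent_chunks(n):
        m = P.shape[0]
        S = np.tile(c, (m, 1))
        rows = np.arange(m)
        for k in range(1, n + 1):
            np.subtract.at(S, (rows, P[:, k - 1]), c[k])
        mask = (S >= -sf_tolerance).all(axis=1)
        out.extend(tuple(int(v) for v in row) for row in P[mask])
    return out


def enumerate_structures(
    cluster_set: ClusterSet,
    sf_tolerance: float = DEFAULT_SF_TOLERANCE,
    max_n: int = DEFAULT_MAX_N,
) -> SolutionSet:
    """Enumerate every viable subclone tree for one sample.

    Visits all n! candidate topologies and keeps those with an
    everywhere non-negative SF assignment.  An empty cluster set yields
    the single normal-only structure.  ``max_n`` guards against the
    factorial blow-up (raise it explicitly for n > 10).
    """
    n = len(cluster_set)
    if n > max_n:
        raise ValueError(
            f"{n} clusters means {n}! candidate trees; raise max_n to override"
        )
    cps = cluster_set.cps
    # strictly-descending distinct CPs in (0, 1] are enforced by ClusterSet
    trees: List[SubcloneTree] = []
    for parents in viable_parent_vectors(cps, sf_tolerance):
        sf = evaluate_tree(parents, cps, sf_tolerance)
        assert sf is not None
        trees.append(SubcloneTree(cluster_set.labels, cps, parents, sf))
    return SolutionSet(cluster_set.sample_id, cluster_set, trees, math.factorial(n))


def implied_cp(tree: SubcloneTree) -> Tuple[float, ...]:
    """CP vector reproduced by the tree (must equal the input exactly)."""
    return tree.implied_cp()


def mutation_profile(tree: SubcloneTree, node: int) -> FrozenSet[str]:
    """Cumulative mutation profile of ``node`` (path union from the root)."""
    return tree.node_profile(node)


def normal_fraction(tree: SubcloneTree) -> float:
    """SF of the null subclone: the normal-tissue contamination."""
    return tree.normal_fraction
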