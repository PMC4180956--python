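"""Cross-sample trimming of subclone solution sets.

A relapse tumor continues the evolution of the primary, so any viable
relapse tree must be graftable onto a viable primary tree under two
conditions that encode the no-recurrence / no-loss assumptions:

1. every node's children carry all the mutations of the node itself
   (extra mutations are allowed), and
2. no two branches carry the same mutation without sharing a common
   ancestor that already carries it.

Compatibility is tested on cumulative mutation profiles: for every
relapse node, the shared-cluster portion of its profile must equal the
full profile of some primary node (its *anchor*; the empty profile
anchors to the primary root).  Trees with no compatible partner in the
other sample are discarded, often shrinking both solution sets
dramatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .clustering import ClusterSet
from .enumeration import SolutionSet, SubcloneTree

__all__ = [
    "MergedTree",
    "MergedSolution",
    "MergeError",
    "shared_clusters",
    "is_compatible",
    "merge_trees",
    "trim_solution_sets",
]


class MergeError(ValueError):
    """The anchored graft would violate a merge condition."""


@dataclass(frozen=True)
class MergedTree:
    """Structural merged tree: nodes carry cumulative profiles, no SFs.

    ``profiles[v]`` is node v's cumulative mutation profile and
    ``parents[v]`` its parent (root = node 0, parent None).  ``origin``
    tags each node primary / relapse / both.
    """

    profiles: Tuple[FrozenSet[str], ...]
    parents: Tuple[Optional[int], ...]
    origin: Tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.profiles)

    def children(self, node: int) -> List[int]:
        return [v for v, p in enumerate(self.parents) if p == node]

    def node_profiles(self) -> List[FrozenSet[str]]:
        return list(self.profiles)

    def labels(self) -> Tuple[str, ...]:
        out: Set[str] = set()
        for p in self.profiles:
            out |= p
        return tuple(sorted(out))

    def validate(self) -> None:
        """Assert both merge conditions."""
        for v, p in enumerate(self.parents):
            if p is not None and not self.profiles[p] <= self.profiles[v]:
                raise MergeError(f"child {v} lacks mutations of its parent {p}")
        for label in self.labels():
            topmost = [
                v
                for v, prof in enumerate(self.profiles)
                if label in prof
                and (self.parents[v] is None or label not in self.profiles[self.parents[v]])
            ]
            if len(topmost) != 1:
                raise MergeError(
                    f"cluster {label} arises independently on {len(topmost)} branches"
                )

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": v,
                    "profile": sorted(self.profiles[v]),
                    "parent": self.parents[v],
                    "origin": self.origin[v],
                }
                for v in range(self.n_nodes)
            ]
        }


@dataclass
class MergedSolution:
    """One compatible (primary tree, relapse tree) pair and its merged tree."""

    primary_index: int
    relapse_index: int
    merged: MergedTree
    anchors: Dict[int, int]  # relapse node -> primary node it extends


def shared_clusters(primary_set: ClusterSet, relapse_set: ClusterSet) -> Set[str]:
    """Cluster labels present (above the zero threshold) in both samples.

    Both sets must derive from the same joint clustering so that labels
    are comparable; an empty intersection is a valid outcome (fully
    divergent samples), not an error.
    """
    return set(primary_set.labels) & set(relapse_set.labels)


def is_compatible(
    primary_tree: SubcloneTree,
    relapse_tree: SubcloneTree,
    shared: Set[str],
) -> Tuple[bool, Optional[Dict[int, int]]]:
    """Test whether a relapse tree can extend a primary tree.

    For every relapse node r, ``shared & profile(r)`` must equal the full
    cumulative profile of some primary node (unique, since distinct CPs
    make primary profiles distinct).  Returns ``(True, anchor_map)`` or
    ``(False, None)``.
    """
    primary_by_profile = {
        primary_tree.node_profile(v): v for v in range(primary_tree.n + 1)
    }
    anchors: Dict[int, int] = {}
    for r in range(relapse_tree.n + 1):
        shared_part = frozenset(shared & relapse_tree.node_profile(r))
        anchor = primary_by_profile.get(shared_part)
        if anchor is None:
            return False, None
        anchors[r] = anchor
    return True, anchors


def merge_trees(
    primary_tree: SubcloneTree,
    relapse_tree: SubcloneTree,
    anchors: Dict[int, int],
    shared: Set[str],
) -> MergedTree:
    """Graft relapse-specific extensions onto the primary tree.

    Each relapse node with relapse-only clusters becomes a new node with
    profile ``profile(anchor) | relapse-only part``, attached under its
    nearest grafted relapse ancestor, or under its anchor when none
    exists.  The result is validated against both merge conditions;
    a :class:`MergeError` means the pair, although profile-compatible,
    cannot be merged without an independent recurrence.
    """
    profiles = [primary_tree.node_profile(v) for v in range(primary_tree.n + 1)]
    parents: List[Optional[int]] = [
        None if v == 0 else primary_tree.parents[v - 1]
        for v in range(primary_tree.n + 1)
    ]
    origin = ["primary"] * (primary_tree.n + 1)

    merged_node_of_relapse: Dict[int, int] = {}
    # relapse nodes in increasing rank order = parents before children
    for r in range(relapse_tree.n + 1):
        rprof = relapse_tree.node_profile(r)
        specific = rprof - shared
        if not specific:
            merged_node_of_relapse[r] = anchors[r]
            origin[anchors[r]] = "both"
            continue
        new_profile = primary_tree.node_profile(anchors[r]) | specific
        # attach under the nearest grafted relapse ancestor, else the anchor
        pr = relapse_tree.parents[r - 1]
        while pr != 0 and not (relapse_tree.node_profile(pr) - shared):
            pr = relapse_tree.parents[pr - 1]
        if pr == 0 or not (relapse_tree.node_profile(pr) - shared):
            parent = anchors[r]
        else:
            parent = merged_node_of_relapse[pr]
        profiles.append(frozenset(new_profile))
        parents.append(parent)
        origin.append("relapse")
        merged_node_of_relapse[r] = len(profiles) - 1

    merged = MergedTree(tuple(profiles), tuple(parents), tuple(origin))
    merged.validate()
    return merged


def trim_solution_sets(
    primary_solutions: SolutionSet,
    relapse_solutions: SolutionSet,
) -> Tuple[SolutionSet, SolutionSet, List[MergedSolution]]:
    """Discard trees with no compatible partner in the other sample.

    Returns the trimmed primary and relapse solution sets plus every
    compatible (primary, relapse) pair with its merged tree.  A pair
    whose graft violates the merge conditions is treated as
    incompatible.  Zero surviving pairs signals a model violation
    (e.g. mutation loss between samples) and returns empty sets with a
    warning.
    """
    if not primary_solutions.trees or not relapse_solutions.trees:
        raise ValueError("trim requires non-empty solution sets")
    shared = shared_clusters(
        primary_solutions.cluster_set, relapse_solutions.cluster_set
    )
    merged_solutions: List[MergedSolution] = []
    keep_p: Set[int] = set()
    keep_r: Set[int] = set()
    for i, pt in enumerate(primary_solutions.trees):
        for j, rt in enumerate(relapse_solutions.trees):
            ok, anchors = is_compatible(pt, rt, shared)
            if not ok:
                continue
            try:
                merged = merge_trees(pt, rt, anchors, shared)
            except MergeError:
                continue
            keep_p.add(i)
            keep_r.add(j)
            merged_solutions.append(MergedSolution(i, j, merged, anchors))
    if not merged_solutions:
        warnings.warn(
            "no compatible primary/relapse pair: the two samples violate the "
            "no-recurrence/no-loss model (or clustering mis-assigned clusters)"
        )
    trimmed_p = SolutionSet(
        primary_solutions.sample_id,
        primary_solutions.cluster_set,
        [primary_solutions.trees[i] for i in sorted(keep_p)],
        primary_solutions.visited,
    )
    trimmed_r = SolutionSet(
        relapse_solutions.sample_id,
        relapse_solutions.cluster_set,
        [relapse_solutions.trees[j] for j in sorted(keep_r)],
        relapse_solutions.visited,
    )
    return trimmed_p, trimmed_r, merged_solutions
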