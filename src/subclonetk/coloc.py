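"""Mutation co-localization and temporal ordering over a solution set.

When several viable subclone structures explain the data equally well,
the full solution set still carries statistical information: the
fraction of structures in which two clusters sit together in at least
one subclone is the co-localization frequency (CLF),

    CLF(a, b) = sum_i PS_i * CL_i(a, b)

with ``PS_i`` the prior probability of solution i (uniform,
1 / #solutions, unless stated otherwise) and ``CL_i`` a 0/1 indicator.
Thresholding the CLF yields three-way calls (co-localized / not
co-localized / ambiguous), and within a co-localized pair the cluster
with the higher CP necessarily arose earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .clustering import ClusterSet

__all__ = [
    "CLFMatrix",
    "ColocCall",
    "clf_matrix",
    "call_colocalization",
    "order_events",
    "consensus_structure",
    "root_children_prior",
]


@dataclass
class CLFMatrix:
    """Symmetric pairwise co-localization frequency matrix."""

    labels: Tuple[str, ...]
    matrix: np.ndarray
    n_solutions: int
    priors: np.ndarray

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def pairs(self) -> List[Tuple[str, str, float]]:
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                out.append((self.labels[i], self.labels[j], float(self.matrix[i, j])))
        return out


@dataclass(frozen=True)
class ColocCall:
    cluster_a: str
    cluster_b: str
    clf: float
    status: str  # "co-localized" | "not co-localized" | "ambiguous"
    threshold: float


def _solution_list(solutions) -> list:
    trees = getattr(solutions, "trees", solutions)
    return list(trees)


def _solution_labels(trees, labels: Optional[Sequence[str]]) -> Tuple[str, ...]:
    if labels is not None:
        return tuple(labels)
    first = trees[0]
    if hasattr(first, "labels") and not callable(first.labels):
        return tuple(first.labels)
    out = set()
    for prof in first.node_profiles():
        out |= prof
    return tuple(sorted(out))


def clf_matrix(solutions, priors=None, labels: Optional[Sequence[str]] = None) -> CLFMatrix:
    """Co-localization frequency matrix over a solution set.

    ``solutions`` is a SolutionSet, a list of subclone trees, or a list
    of merged trees — anything whose elements expose ``node_profiles()``.
    A pair co-localizes in one solution when some node's cumulative
    mutation profile contains both clusters.  ``priors`` (PS_i) default
    to uniform and must be non-negative and sum to 1.
    """
    trees = _solution_list(solutions)
    if not trees:
        raise ValueError("need at least one solution")
    labs = _solution_labels(trees, labels)
    m = len(trees)
    if priors is None:
        ps = np.full(m, 1.0 / m)
    else:
        ps = np.asarray(priors, dtype=float)
        if ps.shape != (m,):
            raise ValueError(f"priors length {ps.size} != number of solutions {m}")
        if np.any(ps < 0) or not math.isclose(float(ps.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("priors must be non-negative and sum to 1")
    index = {l: i for i, l in enumerate(labs)}
    clf = np.zeros((len(labs), len(labs)))
    for w, tree in zip(ps, trees):
        co = np.zeros_like(clf, dtype=bool)
        for prof in tree.node_profiles():
            ids = [index[l] for l in prof if l in index]
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    co[ids[a], ids[b]] = co[ids[b], ids[a]] = True
        clf += w * co
    np.fill_diagonal(clf, 1.0)
    return CLFMatrix(labs, clf, m, ps)


def call_colocalization(clf: CLFMatrix, threshold: float = 0.7) -> List[ColocCall]:
    """Three-way co-localization calls for every unordered cluster pair.

    ``co-localized`` when CLF >= t, ``not co-localized`` when
    CLF <= 1 - t, ``ambiguous`` in between (at t = 0.5 the band is empty
    except for CLF exactly 0.5, which stays ambiguous).
    """
    if not (0.5 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0.5, 1]")
    calls = []
    for a, b, v in clf.pairs():
        if threshold == 0.5 and math.isclose(v, 0.5, abs_tol=1e-12):
            status = "ambiguous"
        elif v >= threshold:
            status = "co-localized"
        elif v <= 1.0 - threshold:
            status = "not co-localized"
        else:
            status = "ambiguous"
        calls.append(ColocCall(a, b, v, status, threshold))
    return calls


def order_events(
    cluster_a: str,
    cluster_b: str,
    cluster_set: ClusterSet,
    calls: Iterable[ColocCall],
) -> str:
    """Temporal order of two clusters: 'a_first', 'b_first' or 'undetermined'.

    Only a co-localized pair can be ordered: within one lineage the
    event with the higher CP appeared earlier.
    """
    for label in (cluster_a, cluster_b):
        if label not in cluster_set.labels:
            raise KeyError(f"cluster {label} not in cluster set")
    pair = {cluster_a, cluster_b}
    status = next(
        (c.status for c in calls if {c.cluster_a, c.cluster_b} == pair), None
    )
    if status != "co-localized":
        return "undetermined"
    cp = dict(zip(cluster_set.labels, cluster_set.cps))
    return "a_first" if cp[cluster_a] > cp[cluster_b] else "b_first"


def consensus_structure(solutions, support_threshold: float = 1.0) -> List[Tuple[str, str, float]]:
    """Lineage relations supported by at least ``support_threshold`` of solutions.

    A relation (x, y) means cluster x precedes cluster y on the same
    lineage (x is in the cumulative profile of y's node).  Returns
    (earlier, later, support) triples with support >= threshold; they
    assemble into a partial-order diagram of the consensus evolution.
    """
    if not (0.5 <= support_threshold <= 1.0):
        raise ValueError(f"support threshold {support_threshold} outside [0.5, 1]")
    trees = _solution_list(solutions)
    if not trees:
        raise ValueError("need at least one solution")
    labs = _solution_labels(trees, None)
    counts: Dict[Tuple[str, str], int] = {}
    for tree in trees:
        profiles = tree.node_profiles()
        for y in labs:
            yprofs = [p for p in profiles if y in p]
            if not yprofs:
                continue
            own = min(yprofs, key=len)  # the node where y first appears
            for x in own:
                if x != y:
                    counts[(x, y)] = counts.get((x, y), 0) + 1
    total = len(trees)
    out = [
        (x, y, c / total)
        for (x, y), c in sorted(counts.items())
        if c / total >= support_threshold
    ]
    return out


def root_children_prior(solutions, lam: float = 0.0) -> np.ndarray:
    """Optional solution prior down-weighting many independent origins.

    ``PS_i`` proportional to ``exp(-lam * number of root children)``:
    structures where many subclones descend directly from normal tissue
    are biologically less likely.  ``lam = 0`` reproduces the uniform
    prior.
    """
    trees = _solution_list(solutions)
    w = np.array([math.exp(-lam * len(t.children(0))) for t in trees], dtype=float)
    return w / w.sum()
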