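"""Grouping of CP events into clusters (CP modals).

Bulk CP measurements are noisy; events created by the same mutational
burst share a true CP, so events are clustered and each cluster's CP is
the mean of its members.  One sample is clustered by 1-D Gaussian KDE
mode-finding (Sheather-Jones bandwidth); multiple samples from one
patient are clustered jointly in the k-dimensional CP space by
mean-shift with a product Gaussian kernel, so that clusters that are
present in one sample but absent from another ("separately inherited")
stay separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bandwidth import select_bandwidth, silverman_bandwidth
from .cellprev import CPEvent

__all__ = [
    "CPCluster",
    "ClusterSet",
    "kde_cluster_1d",
    "cluster_multisample",
    "project_cluster_set",
    "clusters_from_table",
]

#: number of density grid points over the padded CP axis
GRID_SIZE = 512
GRID_LO, GRID_HI = -0.05, 1.05


@dataclass
class CPCluster:
    """A group of events sharing a CP modal; one CP per sample."""

    cluster_id: str
    cp_by_sample: Dict[str, float]
    member_event_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_event_ids:
            raise ValueError(f"cluster {self.cluster_id}: empty member set")
        for s, cp in self.cp_by_sample.items():
            if not (0.0 <= cp <= 1.0):
                raise ValueError(f"cluster {self.cluster_id}: CP {cp} in {s} outside [0, 1]")
        if all(cp <= 0.0 for cp in self.cp_by_sample.values()):
            raise ValueError(f"cluster {self.cluster_id}: CP is zero in every sample")


@dataclass(frozen=True)
class ClusterSet:
    """One sample's view: cluster labels ordered by strictly descending CP.

    This ordered list of distinct CP values in (0, 1] is the direct input
    to subclone structure enumeration.
    """

    sample_id: str
    labels: Tuple[str, ...]
    cps: Tuple[float, ...]
    members: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cps):
            raise ValueError("labels and cps length mismatch")
        for cp in self.cps:
            if not (0.0 < cp <= 1.0):
                raise ValueError(f"cluster CP {cp} outside (0, 1]")
        for a, b in zip(self.cps, self.cps[1:]):
            if not a > b:
                raise ValueError("cluster CPs must be strictly descending")

    def __len__(self) -> int:
        return len(self.labels)


def _gaussian_kde_grid(x: np.ndarray, h: float) -> Tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(GRID_LO, GRID_HI, GRID_SIZE)
    z = (grid[None, :] - x[:, None]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (x.size * h * np.sqrt(2 * np.pi))
    return grid, dens


def _local_maxima(dens: np.ndarray) -> List[int]:
    """Strict local maxima; a plateau maximum takes its leftmost grid point."""
    idx = []
    i, m = 0, dens.size
    while i < m:
        j = i
        while j + 1 < m and dens[j + 1] == dens[i]:
            j += 1
        left_ok = i == 0 or dens[i] > dens[i - 1]
        right_ok = j == m - 1 or dens[j] > dens[j + 1]
        if left_ok and right_ok and not (i == 0 and j == m - 1):
            idx.append(i)
        i = j + 1
    return idx


def kde_cluster_1d(
    cp_values: Sequence[float], bandwidth_method: str = "sj"
) -> List[Tuple[float, List[int]]]:
    """Cluster 1-D CP values by KDE modes.

    The Gaussian KDE is evaluated on a fixed grid over the padded unit
    interval; each local density maximum is a modal center, and each
    value is assigned to the modal whose basin (delimited by the density
    minima flanking the maximum) contains it.  Returns ``(center,
    member_indices)`` pairs, where ``center`` is the mean CP of members.
    """
    x = np.asarray(list(cp_values), dtype=float)
    if x.size == 0:
        raise ValueError("no CP values to cluster")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("CP values must lie in [0, 1]")
    h = select_bandwidth(x, bandwidth_method) if x.size > 1 else 0.0
    if h == 0.0:
        return [(float(np.mean(x)), list(range(x.size)))]
    grid, dens = _gaussian_kde_grid(x, h)
    maxima = _local_maxima(dens)
    if len(maxima) <= 1:
        return [(float(np.mean(x)), list(range(x.size)))]
    # basin boundaries: density minimum between consecutive maxima
    bounds = []
    for a, b in zip(maxima, maxima[1:]):
        k = a + int(np.argmin(dens[a : b + 1]))
        bounds.append(grid[k])
    assign = np.searchsorted(np.asarray(bounds), x, side="right")
    clusters = []
    for m in range(len(maxima)):
        members = np.nonzero(assign == m)[0]
        if members.size:
            clusters.append((float(np.mean(x[members])), members.tolist()))
    return clusters


def _mean_shift(points: np.ndarray, bandwidths: np.ndarray) -> np.ndarray:
    """Mean-shift each point to its mode under a product Gaussian kernel."""
    modes = points.copy()
    for i in range(points.shape[0]):
        y = points[i].copy()
        for _ in range(500):
            z = (y[None, :] - points) / bandwidths[None, :]
            w = np.exp(-0.5 * (z * z).sum(axis=1))
            y_new = (w[:, None] * points).sum(axis=0) / w.sum()
            if np.max(np.abs(y_new - y)) < 1e-8:
                y = y_new
                break
            y = y_new
        modes[i] = y
    return modes


def cluster_multisample(
    events: Sequence[CPEvent],
    bandwidth_method: str = "sj",
    require_complete: bool = False,
) -> List[CPCluster]:
    """Cluster events jointly across samples in k-dimensional CP space.

    Events are keyed by ``event_id``; an event missing from a sample gets
    CP 0 there (set ``require_complete`` to raise instead).  With a
    single sample this reduces to 1-D KDE clustering; otherwise
    mean-shift with per-dimension bandwidths is used.  Cluster CPs are
    per-sample member means.
    """
    if not events:
        raise ValueError("no events to cluster")
    samples = sorted({e.sample_id for e in events})
    by_event: Dict[str, Dict[str, float]] = {}
    for e in events:
        by_event.setdefault(e.event_id, {})[e.sample_id] = e.cp
    event_ids = sorted(by_event)
    if require_complete:
        for eid, row in by_event.items():
            if set(row) != set(samples):
                raise ValueError(f"event {eid} lacks a CP in some samples")
    mat = np.array(
        [[by_event[eid].get(s, 0.0) for s in samples] for eid in event_ids], dtype=float
    )

    if len(samples) == 1:
        groups = kde_cluster_1d(mat[:, 0], bandwidth_method)
        assignments = [members for _, members in groups]
    else:
        bws = []
        for d in range(len(samples)):
            h = select_bandwidth(mat[:, d], bandwidth_method)
            bws.append(h if h > 0 else 0.05)
        bws = np.asarray(bws)
        modes = _mean_shift(mat, bws)
        merge_tol = max(1e-3, float(bws.min()) / 2.0)
        centers: List[np.ndarray] = []
        assignments = []
        for i in range(modes.shape[0]):
            for c, members in zip(centers, assignments):
                if np.linalg.norm(modes[i] - c) < merge_tol:
                    members.append(i)
                    break
            else:
                centers.append(modes[i])
                assignments.append([i])

    # order clusters deterministically: per-sample mean CP tuple, descending
    summaries = []
    for members in assignments:
        cps = tuple(float(np.mean(mat[members, d])) for d in range(len(samples)))
        summaries.append((cps, members))
    summaries.sort(key=lambda t: t[0], reverse=True)

    clusters = []
    for k, (cps, members) in enumerate(summaries, 1):
        clusters.append(
            CPCluster(
                cluster_id=f"K{k}",
                cp_by_sample={s: min(1.0, max(0.0, cp)) for s, cp in zip(samples, cps)},
                member_event_ids=tuple(event_ids[i] for i in members),
            )
        )
    return clusters


def project_cluster_set(
    clusters: Sequence[CPCluster],
    sample_id: str,
    zero_threshold: float = 0.05,
    tie_epsilon: float = 1e-3,
) -> ClusterSet:
    """Project multi-sample clusters onto one sample as an ordered ClusterSet.

    Clusters at or below ``zero_threshold`` CP in this sample are treated
    as absent.  Clusters whose CPs differ by less than ``tie_epsilon``
    are merged (member union, mean CP) with a warning, since enumeration
    requires strictly distinct CPs.
    """
    if not (0.0 <= zero_threshold <= 0.1):
        raise ValueError(f"zero_threshold {zero_threshold} outside [0, 0.1]")
    kept = [
        (c.cluster_id, c.cp_by_sample.get(sample_id, 0.0), c.member_event_ids)
        for c in clusters
        if c.cp_by_sample.get(sample_id, 0.0) > zero_threshold
    ]
    kept.sort(key=lambda t: t[1], reverse=True)

    merged: List[Tuple[List[str], List[float], List[str]]] = []
    for label, cp, members in kept:
        if merged and abs(merged[-1][1][-1] - cp) < tie_epsilon:
            warnings.warn(
                f"clusters {merged[-1][0][-1]} and {label} have indistinguishable CP "
                f"in sample {sample_id}; merged"
            )
            merged[-1][0].append(label)
            merged[-1][1].append(cp)
            merged[-1][2].extend(members)
        else:
            merged.append(([label], [cp], list(members)))

    labels, cps, members_map = [], [], {}
    for labs, vals, membs in merged:
        label = "+".join(labs)
        labels.append(label)
        cps.append(float(np.mean(vals)))
        members_map[label] = tuple(membs)
    return ClusterSet(sample_id, tuple(labels), tuple(cps), members_map)


def clusters_from_table(rows) -> List[CPCluster]:
    """Build clusters from (cluster_id, sample, cp) rows — the bypass input
    for CP estimates produced by external tools or published tables."""
    by_id: Dict[str, Dict[str, float]] = {}
    for cluster_id, sample, cp in rows:
        by_id.setdefault(str(cluster_id), {})[str(sample)] = float(cp)
    return [
        CPCluster(cid, cps, (cid,)) for cid, cps in sorted(by_id.items())
    ]
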