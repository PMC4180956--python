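"""Synthetic tumors with known subclone structure, and the two
validation experiments built on them.

The generator draws a uniform random increasing tree (cluster k attaches
to the root or any earlier node with equal probability), assigns
subclone frequencies to all n+1 nodes from a flat Dirichlet, and derives
each cluster's CP as its subtree SF sum.  Draws are rejected until all
pairwise CP gaps reach ``min_cp_gap`` (0.02 by default), since the
enumeration model requires distinct CPs.  Everything is deterministic
given the seed; per-replicate seeds derive from the master seed and the
replicate index.

Experiments:

* ``recovery_experiment`` — is the true structure always among the
  enumerated viable structures?  (It must be: the truth has non-negative
  SFs by construction, hence is itself viable.)  Also records the
  viable-set size distribution, which is heavily compressed far below
  the n! ceiling.
* ``coloc_benchmark`` — sensitivity / positive predictive value of
  thresholded co-localization calls against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .clustering import ClusterSet
from .coloc import call_colocalization, clf_matrix
from .enumeration import SolutionSet, SubcloneTree, enumerate_structures

__all__ = [
    "SimulatedTumor",
    "RecoveryReport",
    "BenchmarkReport",
    "simulate_structure",
    "recovery_experiment",
    "coloc_benchmark",
]

DEFAULT_MIN_CP_GAP = 0.02
_MAX_DRAWS = 10_000


@dataclass(frozen=True)
class SimulatedTumor:
    """A synthetic tumor: the true tree, and the CP vector it implies."""

    truth: SubcloneTree
    cluster_set: ClusterSet
    n_clusters: int
    seed: Optional[int]


@dataclass
class RecoveryReport:
    replicates: int
    recovered: int
    viable_counts: List[int]
    n_per_replicate: List[int]
    seed: int


@dataclass
class BenchmarkReport:
    """Pooled co-localization call performance against simulated truth.

    ``sensitivity`` is correct non-ambiguous calls over all pairs (an
    ambiguous call on a decidable pair costs sensitivity), while ``ppv``
    is correct calls over all non-ambiguous calls.
    """

    n_subclones: int
    replicates: int
    threshold: float
    sensitivity: float
    ppv: float
    total_pairs: int
    n_calls: int
    n_correct: int
    true_coloc: int
    true_not_coloc: int
    called_coloc: int
    called_not_coloc: int
    called_ambiguous: int
    seed: int


def _rng_for(seed, replicate: Optional[int] = None) -> np.random.Generator:
    if replicate is None:
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def simulate_structure(
    n_clusters: int,
    seed: Optional[int] = None,
    min_cp_gap: float = DEFAULT_MIN_CP_GAP,
    min_normal_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    max_draws: int = _MAX_DRAWS,
) -> SimulatedTumor:
    """Draw one synthetic tumor with ``n_clusters`` mutation clusters."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if rng is None:
        rng = _rng_for(seed)
    for _ in range(max_draws):
        raw_parents = [int(rng.integers(0, k)) for k in range(1, n_clusters + 1)]
        sf = rng.dirichlet(np.ones(n_clusters + 1))
        if sf[0] < min_normal_fraction:
            continue
        # CP = subtree SF sum
        cp = sf.copy()
        for k in range(n_clusters, 0, -1):
            cp[raw_parents[k - 1]] += cp[k]
        cps = cp[1:]
        gaps = np.abs(cps[:, None] - cps[None, :])
        np.fill_diagonal(gaps, 1.0)
        if gaps.min() < min_cp_gap or cps.min() <= 0:
            continue
        # relabel nodes by CP rank (rank 1 = highest CP)
        order = np.argsort(-cps)  # order[r-1] = original node index - 1
        rank_of = {int(order[r]) + 1: r + 1 for r in range(n_clusters)}
        rank_of[0] = 0
        parents = tuple(
            rank_of[raw_parents[int(order[r])]] for r in range(n_clusters)
        )
        labels = tuple(f"C{r}" for r in range(1, n_clusters + 1))
        ranked_cps = tuple(float(cps[int(order[r])]) for r in range(n_clusters))
        ranked_sf = (float(sf[0]),) + tuple(
            float(sf[int(order[r]) + 1]) for r in range(n_clusters)
        )
        truth = SubcloneTree(labels, ranked_cps, parents, ranked_sf)
        cluster_set = ClusterSet("simulated", labels, ranked_cps)
        return SimulatedTumor(truth, cluster_set, n_clusters, seed)
    raise RuntimeError(
        f"could not draw {n_clusters} clusters with CP gap >= {min_cp_gap} "
        f"in {max_draws} attempts; relax the gap or lower n"
    )


def recovery_experiment(
    n_values: Sequence[int],
    replicates: int,
    seed: int,
    min_cp_gap: float = DEFAULT_MIN_CP_GAP,
) -> RecoveryReport:
    """Simulate tumors (n drawn uniformly from ``n_values``) and check
    that the true structure is among the enumerated viable structures."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    n_values = list(n_values)
    recovered = 0
    viable_counts: List[int] = []
    ns: List[int] = []
    for rep in range(replicates):
        rng = _rng_for(seed, rep)
        n = int(n_values[int(rng.integers(0, len(n_values)))])
        tumor = simulate_structure(n, rng=rng, min_cp_gap=min_cp_gap)
        solutions = enumerate_structures(tumor.cluster_set)
        truth_canon = tumor.truth.canonical()
        if any(t.canonical() == truth_canon for t in solutions.trees):
            recovered += 1
        viable_counts.append(solutions.viable)
        ns.append(n)
    return RecoveryReport(replicates, recovered, viable_counts, ns, seed)


def _true_pair_status(truth: SubcloneTree) -> Dict[Tuple[str, str], bool]:
    """Pair -> truly co-localized (one cluster ancestor-or-equal of the other)."""
    out: Dict[Tuple[str, str], bool] = {}
    profiles = truth.node_profiles()
    labs = truth.labels
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            a, b = labs[i], labs[j]
            co = any(a in p and b in p for p in profiles)
            out[(a, b)] = co
    return out


def coloc_benchmark(
    n_subclones: int,
    replicates: int,
    threshold: float,
    seed: int,
    min_cp_gap: float = DEFAULT_MIN_CP_GAP,
) -> BenchmarkReport:
    """Benchmark thresholded co-localization calls on simulated tumors.

    For each replicate the CLF matrix over the full enumerated solution
    set is thresholded and compared with the true pair statuses; counts
    are pooled over replicates.
    """
    if not (0.5 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0.5, 1]")
    total_pairs = n_calls = n_correct = 0
    true_co = true_not = 0
    called_co = called_not = called_amb = 0
    for rep in range(replicates):
        rng = _rng_for(seed, rep)
        tumor = simulate_structure(n_subclones, rng=rng, min_cp_gap=min_cp_gap)
        truth_status = _true_pair_status(tumor.truth)
        solutions = enumerate_structures(tumor.cluster_set)
        clf = clf_matrix(solutions)
        calls = call_colocalization(clf, threshold)
        for call in calls:
            key = (call.cluster_a, call.cluster_b)
            truly_co = truth_status[key] if key in truth_status else truth_status[
                (call.cluster_b, call.cluster_a)
            ]
            total_pairs += 1
            true_co += truly_co
            true_not += not truly_co
            if call.status == "ambiguous":
                called_amb += 1
                continue
            n_calls += 1
            called = call.status == "co-localized"
            called_co += called
            called_not += not called
            n_correct += called == truly_co
    return BenchmarkReport(
        n_subclones=n_subclones,
        replicates=replicates,
        threshold=threshold,
        sensitivity=n_correct / total_pairs if total_pairs else 0.0,
        ppv=n_correct / n_calls if n_calls else 0.0,
        total_pairs=total_pairs,
        n_calls=n_calls,
        n_correct=n_correct,
        true_coloc=true_co,
        true_not_coloc=true_not,
        called_coloc=called_co,
        called_not_coloc=called_not,
        called_ambiguous=called_amb,
        seed=seed,
    )
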