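"""Cluster refinement: silhouette-guided merging and singleton absorption.

Refinement inspects every sequence *i* of every multi-member cluster *k* and
compares its cohesion a_i (mean composed distance to the rest of *k*) with its
separation b_i (smallest mean distance to the members of any other cluster).
a_i > b_i is an inconsistency: *k* is merged with the cluster attaining b_i
and the scan restarts, until a full pass finds no violation.

A second pass tries to absorb singleton clusters, which the first pass can
never move (their a_i is 0).  A singleton joins its nearest cluster *l* when
doing so barely changes *l*'s uniformity -- a dispersion statistic of the
nearest-neighbour distances within the cluster:

    local_den(i) = min_{j in k, j != i} d(i, j)
    avg_den(k)   = mean_i local_den(i)
    unif(k)      = sum_i |local_den(i) - avg_den(k)| / avg_den(k)   (0 if n = 1)

Smaller uniformity means more evenly spaced members.  The printed literal
form of the uniformity sum uses signed deviations, which cancel to zero by
definition of the mean; the absolute-deviation form implemented here is the
meaningful variability measure (a ``literal_uniformity`` flag restores the
signed form for auditing).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .datamodel import Clustering, ConfigError, ConsistencyError, Repertoire
from .distances import DistanceConfig, pairwise_matrix
from .precluster import PreclusterConfig, precluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefineConfig:
    """Refinement parameters.

    ``delta`` is the singleton-merge tolerance on the uniformity change
    (default 0.05); ``max_iter`` caps the number of merge passes.
    """

    delta: float = 0.05
    max_iter: int = 1000
    refinement: bool = True
    merge_singletons: bool = True
    literal_uniformity: bool = False

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ConfigError("delta must be >= 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")


# ---------------------------------------------------------------------------
# scalar operations (spec surface); the engine below vectorizes the same math
# ---------------------------------------------------------------------------

def intra_distance(
    rep: Repertoire, seq_id: str, member_ids: Iterable[str], dcfg: DistanceConfig | None = None
) -> float:
    """Mean composed distance from *seq_id* to the other members of its cluster."""
    from .distances import composed_distance

    dcfg = dcfg or DistanceConfig()
    others = [m for m in member_ids if m != seq_id]
    if not others:
        raise ValueError("intra_distance undefined for singleton clusters")
    seq = rep[seq_id]
    return sum(composed_distance(seq, rep[m], dcfg) for m in others) / len(others)


def inter_distance(
    rep: Repertoire, seq_id: str, clustering: Clustering, dcfg: DistanceConfig | None = None
) -> Tuple[float, str]:
    """Smallest mean composed distance from *seq_id* to any other cluster.

    Returns ``(b_i, nearest_label)``; ties on the mean break toward the
    smallest cluster label.  The mean (not the minimum) over the foreign
    cluster's members is used, consistent with the silhouette b term.
    """
    from .distances import composed_distance

    dcfg = dcfg or DistanceConfig()
    own = clustering.assignment[seq_id]
    seq = rep[seq_id]
    best: Optional[Tuple[float, str]] = None
    for label in clustering.labels:
        if label == own:
            continue
        members = clustering.clusters[label]
        mean = sum(composed_distance(seq, rep[m], dcfg) for m in members) / len(members)
        if best is None or mean < best[0]:
            best = (mean, label)
    if best is None:
        raise ValueError("inter_distance undefined with a single cluster")
    return best


def local_density(
    rep: Repertoire, seq_id: str, member_ids: Iterable[str], dcfg: DistanceConfig | None = None
) -> float:
    """Minimum composed distance from *seq_id* to another member of its cluster."""
    from .distances import composed_distance

    dcfg = dcfg or DistanceConfig()
    others = [m for m in member_ids if m != seq_id]
    if not others:
        raise ValueError("local_density undefined for singleton clusters")
    seq = rep[seq_id]
    return min(composed_distance(seq, rep[m], dcfg) for m in others)


def avg_density(
    rep: Repertoire, member_ids: Iterable[str], dcfg: DistanceConfig | None = None
) -> float:
    """Mean of the members' local densities."""
    member_ids = list(member_ids)
    return sum(local_density(rep, m, member_ids, dcfg) for m in member_ids) / len(member_ids)


def uniformity(
    rep: Repertoire,
    member_ids: Iterable[str],
    dcfg: DistanceConfig | None = None,
    literal: bool = False,
) -> float:
    """Cluster uniformity; 0 for singletons and for clusters of duplicates
    (average density 0)."""
    member_ids = list(member_ids)
    if len(member_ids) <= 1:
        return 0.0
    local = [local_density(rep, m, member_ids, dcfg) for m in member_ids]
    avg = sum(local) / len(local)
    if avg == 0.0:
        return 0.0
    dev = (x - avg for x in local) if literal else (abs(x - avg) for x in local)
    return sum(dev) / avg


# ---------------------------------------------------------------------------
# matrix engine
# ---------------------------------------------------------------------------

class _State:
    """Mutable clustering state over a fixed distance matrix."""

    def __init__(self, rep: Repertoire, clustering: Clustering, dist: np.ndarray):
        self.rep = rep
        self.dist = dist
        self.pos = {seq_id: p for p, seq_id in enumerate(rep.ids)}
        self.clusters: Dict[str, List[int]] = {
            label: sorted(self.pos[m] for m in clustering.clusters[label])
            for label in clustering.labels
        }

    def merge(self, a: str, b: str, into: Optional[str] = None) -> str:
        """Merge clusters *a* and *b* under label *into* (default: min label)."""
        into = into or min(a, b)
        merged = sorted(self.clusters.pop(a) + self.clusters.pop(b))
        self.clusters[into] = merged
        return into

    def mean_to_clusters(self) -> Tuple[List[str], np.ndarray, np.ndarray]:
        """Mean distance from every sequence to every cluster (n x c)."""
        labels = sorted(self.clusters)
        n = self.dist.shape[0]
        sizes = np.array([len(self.clusters[l]) for l in labels], dtype=float)
        sums = np.empty((n, len(labels)))
        for c, label in enumerate(labels):
            sums[:, c] = self.dist[:, self.clusters[label]].sum(axis=1)
        return labels, sums, sizes

    def to_clustering(self) -> Clustering:
        ids = self.rep.ids
        assignment: Dict[str, str] = {}
        for label in sorted(self.clusters):
            for p in self.clusters[label]:
                assignment[ids[p]] = label
        # keep repertoire order in the assignment for stable member order
        return Clustering({i: assignment[i] for i in ids if i in assignment})

    def uniformity_of(self, positions: List[int], literal: bool) -> float:
        if len(positions) <= 1:
            return 0.0
        sub = self.dist[np.ix_(positions, positions)]
        np.fill_diagonal(sub, np.inf)
        local = sub.min(axis=1)
        avg = local.mean()
        if avg == 0.0:
            return 0.0
        dev = (local - avg) if literal else np.abs(local - avg)
        return float(dev.sum() / avg)


def _refine_passes(state: _State, rcfg: RefineConfig) -> Tuple[int, int, bool]:
    """Iterate merge passes until a fixed point; returns (passes, merges, converged)."""
    merges = 0
    for iteration in range(rcfg.max_iter):
        if len(state.clusters) < 2:
            return iteration, merges, True
        labels, sums, sizes = state.mean_to_clusters()
        col = {label: c for c, label in enumerate(labels)}
        merged_this_pass = False
        for label in labels:
            members = state.clusters[label]
            if len(members) < 2:
                continue
            k = col[label]
            a = sums[members, k] / (sizes[k] - 1)  # own column: D[i,i]=0 drops out
            means = sums[members][:, :] / sizes
            means[:, k] = np.inf
            b = means.min(axis=1)
            viol = np.nonzero(a > b)[0]
            if viol.size:
                row = viol[0]  # first violating sequence in sorted member order
                candidates = np.nonzero(means[row] == b[row])[0]
                nearest = min(labels[c] for c in candidates)
                state.merge(label, nearest)
                merges += 1
                merged_this_pass = True
                break
        if not merged_this_pass:
            return iteration + 1, merges, True
    logger.warning("refinement hit max_iter=%d before converging", rcfg.max_iter)
    return rcfg.max_iter, merges, False


def refine(
    rep: Repertoire,
    clustering: Clustering,
    dcfg: DistanceConfig | None = None,
    rcfg: RefineConfig | None = None,
    dist: Optional[np.ndarray] = None,
) -> Clustering:
    """Merge clusters until no sequence in a multi-member cluster has a_i > b_i.

    Each detected inconsistency merges the offending cluster with the nearest
    one and restarts the scan (clusters and members visited in deterministic
    sorted order), bounded by ``max_iter`` passes.
    """
    dcfg = dcfg or DistanceConfig()
    rcfg = rcfg or RefineConfig()
    clustering.check_partition(rep.ids)
    if dist is None:
        dist = pairwise_matrix(rep, dcfg)
    state = _State(rep, clustering, dist)
    _refine_passes(state, rcfg)
    return state.to_clustering()


def merge_singletons(
    rep: Repertoire,
    clustering: Clustering,
    dcfg: DistanceConfig | None = None,
    rcfg: RefineConfig | None = None,
    dist: Optional[np.ndarray] = None,
) -> Clustering:
    """Absorb singleton clusters into their nearest cluster when the merge
    leaves the target's uniformity within ``delta`` of its previous value.

    Singletons are processed in ascending label order; a cluster enlarged by
    an earlier merge is seen in its enlarged form by later singletons.
    """
    dcfg = dcfg or DistanceConfig()
    rcfg = rcfg or RefineConfig()
    clustering.check_partition(rep.ids)
    if dist is None:
        dist = pairwise_matrix(rep, dcfg)
    state = _State(rep, clustering, dist)
    singleton_labels = sorted(l for l, m in state.clusters.items() if len(m) == 1)
    for label in singleton_labels:
        members = state.clusters.get(label)
        if members is None or len(members) != 1:
            continue  # absorbed or enlarged by an earlier merge
        if len(state.clusters) < 2:
            break
        i = members[0]
        best: Optional[Tuple[float, str]] = None
        for other in sorted(state.clusters):
            if other == label:
                continue
            mean = float(np.mean(dist[i, state.clusters[other]]))
            if best is None or mean < best[0]:
                best = (mean, other)
        _, target = best
        before = state.uniformity_of(state.clusters[target], rcfg.literal_uniformity)
        after = state.uniformity_of(
            sorted(state.clusters[target] + [i]), rcfg.literal_uniformity
        )
        if abs(after - before) < rcfg.delta:
            state.merge(label, target, into=target)
    return state.to_clustering()


def cluster_repertoire(
    rep: Repertoire,
    pcfg: PreclusterConfig | None = None,
    dcfg: DistanceConfig | None = None,
    rcfg: RefineConfig | None = None,
) -> Tuple[Clustering, Dict[str, object]]:
    """Full pipeline: pre-clustering, refinement, singleton merging.

    Returns the final clustering and a run report (cluster counts per stage,
    merge counts, passes, wall time).
    """
    pcfg = pcfg or PreclusterConfig()
    dcfg = dcfg or DistanceConfig()
    rcfg = rcfg or RefineConfig()
    t0 = time.perf_counter()
    initial = precluster(rep, pcfg)
    report: Dict[str, object] = {
        "n_sequences": len(rep),
        "n_reads": rep.n_reads,
        "n_clusters_initial": initial.n_clusters,
    }
    current = initial
    dist = pairwise_matrix(rep, dcfg) if len(rep) else np.zeros((0, 0))
    if rcfg.refinement and len(rep):
        state = _State(rep, current, dist)
        passes, merges, converged = _refine_passes(state, rcfg)
        current = state.to_clustering()
        report.update(
            refine_passes=passes, refine_merges=merges, refine_converged=converged,
            n_clusters_refined=current.n_clusters,
        )
    if rcfg.merge_singletons and len(rep):
        before = current.n_clusters
        current = merge_singletons(rep, current, dcfg, rcfg, dist=dist)
        report["singletons_merged"] = before - current.n_clusters
    report["n_clusters_final"] = current.n_clusters
    report["wall_time_s"] = round(time.perf_counter() - t0, 4)
    report["config"] = {
        "precluster": {"s": pcfg.s, "allele_level": pcfg.allele_level,
                       "cdr3_length_tolerance": pcfg.cdr3_length_tolerance},
        "distance": dcfg.to_dict(),
        "refine": {"delta": rcfg.delta, "max_iter": rcfg.max_iter,
                   "refinement": rcfg.refinement,
                   "merge_singletons": rcfg.merge_singletons},
    }
    return current, report
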