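"""Scoring of inferred clonal partitions against a reference.

Two accuracy modes are provided.  *Pairwise* counts unordered sequence pairs:
a pair is TP when co-clustered in both partitions, FP when co-clustered only
in the inferred one, FN when co-clustered only in the reference; precision,
recall and F-score follow.  *Closeness* first matches inferred clusters to
reference clusters by shared membership, then takes TP/FP/FN as set
intersections and differences of the matched pairs, which makes it sensitive
to clonal composition and repertoire structure, not just pair relations.

Also here: the five-event comparison of two clonal distributions
(identical / join / split / mix / not found), and clonality summaries
(Gini coefficient, Lorenz curve) of the cluster-size distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .datamodel import Clustering, ConsistencyError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    fscore: float
    tp: int
    fp: int
    fn: int
    mode: str

    def to_dict(self) -> Dict[str, object]:
        return {
            "mode": self.mode,
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass(frozen=True)
class EventCounts:
    identical: int
    join: int
    split: int
    mix: int
    not_found: int

    def to_dict(self) -> Dict[str, int]:
        return {
            "identical": self.identical,
            "join": self.join,
            "split": self.split,
            "mix": self.mix,
            "not_found": self.not_found,
        }

    @property
    def total(self) -> int:
        return self.identical + self.join + self.split + self.mix + self.not_found


def _prf(tp: int, fp: int, fn: int, mode: str) -> EvalResult:
    """Precision/recall/F-score with the 0-denominator convention p=r=FS=0."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    fs = 2 * p * r / (p + r) if p + r else 0.0
    if tp + fp == 0 or tp + fn == 0:
        logger.info("degenerate %s counts (tp=%d fp=%d fn=%d); zero convention used",
                    mode, tp, fp, fn)
    return EvalResult(p, r, fs, tp, fp, fn, mode)


def _check_ids(truth: Clustering, inferred: Clustering) -> None:
    t, i = set(truth.assignment), set(inferred.assignment)
    if t != i:
        diff = sorted(t ^ i)
        raise ConsistencyError(
            f"partitions cover different id sets; symmetric difference "
            f"({len(diff)} ids): {diff[:10]}{'...' if len(diff) > 10 else ''}"
        )


def pairwise_metrics(truth: Clustering, inferred: Clustering) -> EvalResult:
    """Pair-counting precision/recall/F-score over all unordered id pairs.

    Computed from the truth-by-inferred contingency table, which is exactly
    equivalent to enumerating the pairs.
    """
    _check_ids(truth, inferred)
    contingency: Dict[Tuple[str, str], int] = {}
    t_sizes: Dict[str, int] = {}
    i_sizes: Dict[str, int] = {}
    for seq_id, t_label in truth.assignment.items():
        i_label = inferred.assignment[seq_id]
        contingency[(t_label, i_label)] = contingency.get((t_label, i_label), 0) + 1
        t_sizes[t_label] = t_sizes.get(t_label, 0) + 1
        i_sizes[i_label] = i_sizes.get(i_label, 0) + 1

    def pairs(n: int) -> int:
        return n * (n - 1) // 2

    tp = sum(pairs(n) for n in contingency.values())
    fp = sum(pairs(n) for n in i_sizes.values()) - tp
    fn = sum(pairs(n) for n in t_sizes.values()) - tp
    return _prf(tp, fp, fn, "pairwise")


def match_clusters(
    truth: Clustering, inferred: Clustering, exact: bool = False
) -> List[Tuple[str, str]]:
    """One-to-one association of inferred and truth clusters by shared members.

    Default is greedy: candidate pairs sorted by overlap descending (ties:
    larger truth cluster first, then lexicographic labels), each cluster used
    at most once, zero-overlap pairs never matched.  ``exact=True`` solves the
    maximum-total-overlap assignment instead (Hungarian algorithm); intended
    for small instances.
    """
    _check_ids(truth, inferred)
    overlaps: Dict[Tuple[str, str], int] = {}
    for seq_id, i_label in inferred.assignment.items():
        key = (i_label, truth.assignment[seq_id])
        overlaps[key] = overlaps.get(key, 0) + 1
    if exact:
        from scipy.optimize import linear_sum_assignment

        i_labels = sorted(inferred.clusters)
        t_labels = sorted(truth.clusters)
        cost = np.zeros((len(i_labels), len(t_labels)))
        for (il, tl), n in overlaps.items():
            cost[i_labels.index(il), t_labels.index(tl)] = -n
        rows, cols = linear_sum_assignment(cost)
        return [
            (i_labels[r], t_labels[c])
            for r, c in zip(rows, cols)
            if cost[r, c] < 0
        ]
    t_sizes = truth.sizes()
    ranked = sorted(
        overlaps.items(),
        key=lambda kv: (-kv[1], -t_sizes[kv[0][1]], kv[0][1], kv[0][0]),
    )
    used_i, used_t = set(), set()
    matches: List[Tuple[str, str]] = []
    for (i_label, t_label), n in ranked:
        if n == 0 or i_label in used_i or t_label in used_t:
            continue
        used_i.add(i_label)
        used_t.add(t_label)
        matches.append((i_label, t_label))
    return matches


def closeness_metrics(
    truth: Clustering, inferred: Clustering, exact_matching: bool = False
) -> EvalResult:
    """Set-difference precision/recall/F-score over best-matched cluster pairs.

    For each matched pair (I, T): TP gains I∩T, FP gains I\\T, FN gains T\\I;
    the three unions are counted.  Unmatched clusters contribute nothing.
    """
    matches = match_clusters(truth, inferred, exact=exact_matching)
    tp_set: set = set()
    fp_set: set = set()
    fn_set: set = set()
    for i_label, t_label in matches:
        i_members = set(inferred.clusters[i_label])
        t_members = set(truth.clusters[t_label])
        tp_set |= i_members & t_members
        fp_set |= i_members - t_members
        fn_set |= t_members - i_members
    return _prf(len(tp_set), len(fp_set), len(fn_set), "closeness")


def compare_distributions(
    d1: Clustering, d2: Clustering
) -> Tuple[EventCounts, Dict[str, str]]:
    """Label every cluster of *d2* with one of five events relative to *d1*.

    Precedence makes the labels a total, mutually exclusive classification:
    ``not_found`` (contains ids absent from d1), then ``identical`` (equals a
    d1 cluster), ``join`` (union of >= 2 whole d1 clusters), ``split``
    (proper subset of one d1 cluster), else ``mix``.
    """
    d1_ids = set(d1.assignment)
    d1_sets = {label: set(m) for label, m in d1.clusters.items()}
    events: Dict[str, str] = {}
    counts = {"identical": 0, "join": 0, "split": 0, "mix": 0, "not_found": 0}
    for label in sorted(d2.clusters):
        members = set(d2.clusters[label])
        if members - d1_ids:
            event = "not_found"
        else:
            source_labels = {d1.assignment[m] for m in members}
            if len(source_labels) == 1:
                src = d1_sets[next(iter(source_labels))]
                event = "identical" if members == src else "split"
            else:
                whole_union = set().union(*(d1_sets[l] for l in source_labels))
                event = "join" if members == whole_union else "mix"
        events[label] = event
        counts[event] += 1
    return EventCounts(**counts), events


def gini(sizes: Sequence[float]) -> float:
    """Mean-absolute-difference Gini coefficient of a size distribution.

    0 for perfectly equal sizes; the attainable maximum is 1 - 1/n.
    """
    x = np.asarray(list(sizes), dtype=float)
    if x.size == 0:
        raise ValueError("gini requires a non-empty size list")
    if (x <= 0).any():
        raise ValueError("gini requires strictly positive sizes")
    x = np.sort(x)
    n = x.size
    # sum_{i,j} |x_i - x_j| / (2 n^2 mean), via the sorted-rank identity
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * x).sum() / (n * n * x.mean()))


def lorenz(sizes: Sequence[float]) -> np.ndarray:
    """Lorenz curve points of a size distribution.

    Returns an (n+1, 2) array of (cumulative fraction of clusters, cumulative
    fraction of sequences) with clusters ordered least to most abundant;
    starts at (0, 0), ends at (1, 1), convex.
    """
    x = np.asarray(list(sizes), dtype=float)
    if x.size == 0:
        raise ValueError("lorenz requires a non-empty size list")
    if (x <= 0).any():
        raise ValueError("lorenz requires strictly positive sizes")
    x = np.sort(x)
    cum = np.concatenate([[0.0], np.cumsum(x)]) / x.sum()
    frac = np.arange(x.size + 1) / x.size
    return np.column_stack([frac, cum])
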