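"""Parameter-grid enumeration and execution for benchmark sweeps.

The canonical sweep varies the pre-clustering identity threshold (5 values),
the distance type of each of the three segments (4 each, 4^3 = 64 metric
combinations), the coefficient scheme (7), and the singleton-merge switch
(2), for 5 * 64 * 7 * 2 = 4480 configurations; over 12 benchmarks that is
53760 runs.  The seven default coefficient schemes are the arithmetic mean
plus the six ways of double-weighting a non-empty proper subset of segments;
arbitrary schemes are accepted.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .datamodel import ConfigError, Repertoire
from .distances import METRICS, DistanceConfig
from .precluster import PreclusterConfig, normalize_threshold
from .refine import RefineConfig, cluster_repertoire

DEFAULT_THRESHOLDS = (0.50, 0.60, 0.70, 0.80, 0.90)
DEFAULT_SCHEMES: Tuple[Tuple[float, float, float], ...] = (
    (1, 1, 1),
    (2, 1, 1), (1, 2, 1), (1, 1, 2),
    (2, 2, 1), (2, 1, 2), (1, 2, 2),
)


@dataclass(frozen=True)
class GridPoint:
    s: float
    v_metric: str
    cdr3_metric: str
    j_metric: str
    alpha: float
    beta: float
    lam: float
    merge_singletons: bool

    def configs(self, delta: float = 0.05) -> Tuple[PreclusterConfig, DistanceConfig, RefineConfig]:
        return (
            PreclusterConfig(s=self.s),
            DistanceConfig(
                v_metric=self.v_metric, cdr3_metric=self.cdr3_metric,
                j_metric=self.j_metric, alpha=self.alpha, beta=self.beta,
                lam=self.lam,
            ),
            RefineConfig(delta=delta, merge_singletons=self.merge_singletons),
        )


def _check_axes(thresholds, metrics, schemes, singleton_options) -> None:
    for axis_name, axis in (
        ("thresholds", thresholds), ("metrics", metrics),
        ("schemes", schemes), ("singleton_options", singleton_options),
    ):
        if not list(axis):
            raise ConfigError(f"grid axis {axis_name!r} is empty")


def grid_configurations(
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    metrics: Sequence[str] = METRICS,
    schemes: Sequence[Tuple[float, float, float]] = DEFAULT_SCHEMES,
    singleton_options: Sequence[bool] = (True, False),
) -> Iterator[GridPoint]:
    """Enumerate the Cartesian product of the sweep axes, deterministically."""
    _check_axes(thresholds, metrics, schemes, singleton_options)
    for s, vm, cm, jm, (a, b, l), ms in itertools.product(
        thresholds, metrics, metrics, metrics, schemes, singleton_options
    ):
        yield GridPoint(normalize_threshold(s), vm, cm, jm, float(a), float(b),
                        float(l), bool(ms))


def grid_size(
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    metrics: Sequence[str] = METRICS,
    schemes: Sequence[Tuple[float, float, float]] = DEFAULT_SCHEMES,
    singleton_options: Sequence[bool] = (True, False),
) -> int:
    """Number of configurations the sweep enumerates (no execution)."""
    _check_axes(thresholds, metrics, schemes, singleton_options)
    return (
        len(list(thresholds)) * len(list(metrics)) ** 3
        * len(list(schemes)) * len(list(singleton_options))
    )


def run_grid(
    benchmarks: Dict[str, Tuple[Repertoire, "Clustering"]],
    points: Optional[Iterable[GridPoint]] = None,
    max_runs: Optional[int] = None,
) -> List[Dict[str, object]]:
    """Run each grid point on each (repertoire, truth) benchmark.

    Returns tidy result rows: the configuration fields plus pairwise and
    closeness precision/recall/F-score.  ``max_runs`` truncates the plan for
    desk-scale subsets.
    """
    from .evaluate import closeness_metrics, pairwise_metrics

    points = list(points) if points is not None else list(grid_configurations())
    rows: List[Dict[str, object]] = []
    done = 0
    for name, (rep, truth) in benchmarks.items():
        for point in points:
            if max_runs is not None and done >= max_runs:
                return rows
            clustering, _ = cluster_repertoire(rep, *point.configs())
            pw = pairwise_metrics(truth, clustering)
            cl = closeness_metrics(truth, clustering)
            rows.append(
                {
                    "benchmark": name,
                    "s": point.s,
                    "v_metric": point.v_metric,
                    "cdr3_metric": point.cdr3_metric,
                    "j_metric": point.j_metric,
                    "alpha": point.alpha,
                    "beta": point.beta,
                    "lambda": point.lam,
                    "merge_singletons": point.merge_singletons,
                    "n_clusters": clustering.n_clusters,
                    "pairwise_precision": pw.precision,
                    "pairwise_recall": pw.recall,
                    "pairwise_fscore": pw.fscore,
                    "closeness_precision": cl.precision,
                    "closeness_recall": cl.recall,
                    "closeness_fscore": cl.fscore,
                }
            )
            done += 1
    return rows
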