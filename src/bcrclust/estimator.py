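"""Scikit-learn style front end for the clonal lineage clustering pipeline."""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .datamodel import Repertoire
from .distances import DistanceConfig
from .precluster import PreclusterConfig
from .refine import RefineConfig, cluster_repertoire


class ClonalLineageClusterer(ClusterMixin, BaseEstimator):
    """Cluster an annotated IGH repertoire into clonal lineages.

    The estimator wraps the three-stage pipeline -- V/J/CDR3-length
    pre-clustering with an identity threshold, silhouette-guided cluster
    merging, and uniformity-gated singleton absorption -- behind the familiar
    ``fit`` / ``fit_predict`` interface so it composes with scikit-learn
    model selection.

    Parameters
    ----------
    s : CDR3 amino-acid identity threshold for pre-clustering; a fraction
        (0.70) or percentage (70).
    v_metric, cdr3_metric, j_metric : per-segment distance type, one of
        ``binary``, ``levenshtein``, ``kmer``, ``giana``.
    alpha, beta, lam : non-negative weights of the V, CDR3 and J parts of the
        composed distance (equal weights give the arithmetic mean).
    kmer_k : k-mer length for the ``kmer`` metric.
    allele_level : compare gene calls at allele rather than gene level.
    cdr3_length_tolerance : pool pre-clustering groups whose CDR3 lengths
        differ by at most this many residues (0 disables).
    delta : uniformity-change tolerance for singleton merging.
    max_iter : cap on refinement merge passes.
    refinement, merge_singletons : enable/disable the two refinement stages.

    Attributes
    ----------
    labels_ : integer cluster index per input sequence, in input order.
    clustering_ : the labelled :class:`~bcrclust.datamodel.Clustering`.
    n_clusters_ : number of inferred clonal lineages.
    report_ : run report (cluster counts per stage, merges, wall time).

    Examples
    --------
    >>> from bcrclust import ClonalLineageClusterer, simulate
    >>> sim = simulate.assemble_repertoire()
    >>> model = ClonalLineageClusterer().fit(sim.repertoire)
    >>> model.n_clusters_ == sim.truth.n_clusters
    True
    """

    def __init__(
        self,
        s: float = 0.70,
        v_metric: str = "binary",
        cdr3_metric: str = "levenshtein",
        j_metric: str = "levenshtein",
        alpha: float = 1.0,
        beta: float = 1.0,
        lam: float = 1.0,
        kmer_k: int = 3,
        allele_level: bool = False,
        cdr3_length_tolerance: int = 0,
        delta: float = 0.05,
        max_iter: int = 1000,
        refinement: bool = True,
        merge_singletons: bool = True,
    ):
        self.s = s
        self.v_metric = v_metric
        self.cdr3_metric = cdr3_metric
        self.j_metric = j_metric
        self.alpha = alpha
        self.beta = beta
        self.lam = lam
        self.kmer_k = kmer_k
        self.allele_level = allele_level
        self.cdr3_length_tolerance = cdr3_length_tolerance
        self.delta = delta
        self.max_iter = max_iter
        self.refinement = refinement
        self.merge_singletons = merge_singletons

    def _configs(self):
        pcfg = PreclusterConfig(
            s=self.s,
            allele_level=self.allele_level,
            cdr3_length_tolerance=self.cdr3_length_tolerance,
        )
        dcfg = DistanceConfig(
            v_metric=self.v_metric,
            cdr3_metric=self.cdr3_metric,
            j_metric=self.j_metric,
            alpha=self.alpha,
            beta=self.beta,
            lam=self.lam,
            kmer_k=self.kmer_k,
            allele_level=self.allele_level,
        )
        rcfg = RefineConfig(
            delta=self.delta,
            max_iter=self.max_iter,
            refinement=self.refinement,
            merge_singletons=self.merge_singletons,
        )
        return pcfg, dcfg, rcfg

    @staticmethod
    def _as_repertoire(X) -> Repertoire:
        if isinstance(X, Repertoire):
            return X
        if isinstance(X, pd.DataFrame):
            from .io_airr import repertoire_from_frame

            return repertoire_from_frame(X)
        raise TypeError(
            "X must be a Repertoire or an AIRR-style pandas DataFrame, "
            f"got {type(X).__name__}"
        )

    def fit(self, X, y=None) -> "ClonalLineageClusterer":
        """Cluster the repertoire *X* (a Repertoire or AIRR DataFrame)."""
        rep = self._as_repertoire(X)
        clustering, report = cluster_repertoire(rep, *self._configs())
        self.clustering_ = clustering
        self.report_ = report
        self.n_clusters_ = clustering.n_clusters
        label_index = {label: k for k, label in enumerate(clustering.labels)}
        self.labels_ = np.array(
            [label_index[clustering.assignment[i]] for i in rep.ids], dtype=int
        )
        self.n_features_in_ = 1
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
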