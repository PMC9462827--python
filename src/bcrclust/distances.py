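"""Per-segment sequence distances and the composed (weighted-mean) distance.

The distance between two annotated sequences is computed piecewise on the
IGHV call, the CDR3 amino-acid string, and the IGHJ call, then combined as

    d(i, j) = (alpha * dV + beta * dCDR3 + lam * dJ) / (alpha + beta + lam)

With equal coefficients this is the arithmetic mean of the three parts.
Four per-segment metrics are available: ``binary`` (same label or not),
``levenshtein`` (edit distance normalized by the longer string), ``kmer``
(one minus the shared fraction of distinct k-mers), and ``giana`` (Euclidean
distance between substitution-matrix spectral embeddings).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Dict, Tuple

import edlib
import numpy as np

from .datamodel import AnnotatedSequence, ConfigError, Repertoire, strip_allele

METRICS = ("binary", "levenshtein", "kmer", "giana")


@dataclass(frozen=True)
class DistanceConfig:
    """Composed-distance configuration.

    alpha, beta, lam weight the V, CDR3 and J parts respectively.  ``kmer_k``
    is the k-mer length for the ``kmer`` metric.  With ``allele_level`` False
    (default), gene labels are compared after stripping the allele suffix.
    """

    v_metric: str = "binary"
    cdr3_metric: str = "levenshtein"
    j_metric: str = "levenshtein"
    alpha: float = 1.0
    beta: float = 1.0
    lam: float = 1.0
    kmer_k: int = 3
    allele_level: bool = False
    giana_rank: int = 6

    def __post_init__(self) -> None:
        for name in (self.v_metric, self.cdr3_metric, self.j_metric):
            if name not in METRICS:
                raise ConfigError(f"unknown metric {name!r}; choose from {METRICS}")
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ConfigError("coefficients must be non-negative")
        if self.alpha + self.beta + self.lam <= 0:
            raise ConfigError("at least one coefficient must be positive")
        if self.kmer_k < 1:
            raise ConfigError("kmer_k must be >= 1")

    def to_dict(self) -> Dict[str, object]:
        return {
            "v_metric": self.v_metric,
            "cdr3_metric": self.cdr3_metric,
            "j_metric": self.j_metric,
            "alpha": self.alpha,
            "beta": self.beta,
            "lambda": self.lam,
            "kmer_k": self.kmer_k,
            "allele_level": self.allele_level,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "DistanceConfig":
        d = dict(d)
        if "lambda" in d:
            d["lam"] = d.pop("lambda")
        return cls(**d)

    def with_coefficients(self, alpha: float, beta: float, lam: float) -> "DistanceConfig":
        return replace(self, alpha=alpha, beta=beta, lam=lam)


def binary_distance(a: str, b: str) -> float:
    """0.0 iff the two labels/strings are equal, else 1.0."""
    if not a or not b:
        raise ValueError("binary_distance requires non-empty inputs")
    return 0.0 if a == b else 1.0


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance divided by the length of the longer string (in [0, 1])."""
    if not a or not b:
        raise ValueError("normalized_levenshtein requires non-empty strings")
    if a == b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """One minus the shared fraction of distinct k-mers (containment over the
    larger k-mer set): 0 for identical strings, 1 when no k-mer is shared."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"strings must be at least k={k} characters long")
    if a == b:
        return 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / max(len(ka), len(kb))


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=8)
def _residue_embedding(rank: int) -> Tuple[Dict[str, np.ndarray], float]:
    """Low-rank spectral factorization of BLOSUM62 as per-residue vectors.

    Returns the residue -> vector map (unknown residues map to the zero
    vector) and the largest pairwise vector distance, used as normalizer.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.array([[blosum[x][y] for y in _AA20] for x in _AA20], dtype=float)
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(-np.abs(eigval))[:rank]
    emb = eigvec[:, order] * np.sqrt(np.abs(eigval[order]))
    vectors = {aa: emb[i].copy() for i, aa in enumerate(_AA20)}
    points = np.vstack([emb, np.zeros((1, rank))])  # zero vector = padding/unknown
    diffs = points[:, None, :] - points[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(axis=2)).max())
    return vectors, dmax


def _embed(seq: str, length: int, rank: int) -> np.ndarray:
    vectors, _ = _residue_embedding(rank)
    out = np.zeros((length, rank))
    offset = (length - len(seq)) // 2  # center padding
    for i, aa in enumerate(seq):
        vec = vectors.get(aa)
        if vec is not None:
            out[offset + i] = vec
    return out


def giana_distance(a: str, b: str, rank: int = 6) -> float:
    """Euclidean distance between fixed-length spectral embeddings of two
    amino-acid strings, rescaled to [0, 1].

    Each residue maps to a rank-``rank`` factor of BLOSUM62; the shorter
    string is center-padded with zero vectors to the longer length.  The
    normalizer is ``dmax * sqrt(L)``, the largest achievable embedding
    distance at that length, so the result never exceeds 1.
    """
    if not a or not b:
        raise ValueError("giana_distance requires non-empty strings")
    if a == b:
        return 0.0
    length = max(len(a), len(b))
    _, dmax = _residue_embedding(rank)
    diff = _embed(a, length, rank) - _embed(b, length, rank)
    return float(np.sqrt((diff**2).sum()) / (dmax * np.sqrt(length)))


def segment_distance(metric: str, a: str, b: str, k: int = 3, rank: int = 6) -> float:
    if metric == "binary":
        return binary_distance(a, b)
    if metric == "levenshtein":
        return normalized_levenshtein(a, b)
    if metric == "kmer":
        return kmer_distance(a, b, k)
    if metric == "giana":
        return giana_distance(a, b, rank)
    raise ConfigError(f"unknown metric {metric!r}")


def composed_distance(
    i: AnnotatedSequence, j: AnnotatedSequence, cfg: DistanceConfig | None = None
) -> float:
    """Weighted mean of the V, CDR3 and J segment distances (Eq. above)."""
    cfg = cfg or DistanceConfig()
    vi, vj = i.v_gene, j.v_gene
    ji, jj = i.j_gene, j.j_gene
    if not cfg.allele_level:
        vi, vj = strip_allele(vi), strip_allele(vj)
        ji, jj = strip_allele(ji), strip_allele(jj)
    d_v = segment_distance(cfg.v_metric, vi, vj, cfg.kmer_k, cfg.giana_rank)
    d_c = segment_distance(cfg.cdr3_metric, i.cdr3_aa, j.cdr3_aa, cfg.kmer_k, cfg.giana_rank)
    d_j = segment_distance(cfg.j_metric, ji, jj, cfg.kmer_k, cfg.giana_rank)
    total = cfg.alpha + cfg.beta + cfg.lam
    return (cfg.alpha * d_v + cfg.beta * d_c + cfg.lam * d_j) / total


def _unique_matrix(values, metric: str, k: int, rank: int) -> Tuple[np.ndarray, np.ndarray]:
    """Distance matrix over the unique values plus the inverse index.

    The unique-level entries are computed with the scalar segment functions so
    the matrix path is bit-identical to repeated :func:`composed_distance`
    calls (the memoization contract).
    """
    uniq, inverse = np.unique(np.asarray(values, dtype=object), return_inverse=True)
    m = len(uniq)
    mat = np.zeros((m, m))
    for p in range(m):
        for q in range(p + 1, m):
            mat[p, q] = mat[q, p] = segment_distance(metric, uniq[p], uniq[q], k, rank)
    return mat, inverse


def pairwise_matrix(rep: Repertoire, cfg: DistanceConfig | None = None) -> np.ndarray:
    """Full composed-distance matrix over the repertoire, in sequence order.

    Duplicated segment values are computed once (distances depend only on the
    V call, CDR3 string and J call), which makes the matrix cheap on real
    repertoires where CDR3s repeat heavily.
    """
    cfg = cfg or DistanceConfig()
    n = len(rep)
    if n == 0:
        return np.zeros((0, 0))
    v_vals = [s.v_gene if cfg.allele_level else strip_allele(s.v_gene) for s in rep]
    j_vals = [s.j_gene if cfg.allele_level else strip_allele(s.j_gene) for s in rep]
    c_vals = [s.cdr3_aa for s in rep]
    mv, iv = _unique_matrix(v_vals, cfg.v_metric, cfg.kmer_k, cfg.giana_rank)
    mc, ic = _unique_matrix(c_vals, cfg.cdr3_metric, cfg.kmer_k, cfg.giana_rank)
    mj, ij = _unique_matrix(j_vals, cfg.j_metric, cfg.kmer_k, cfg.giana_rank)
    total = cfg.alpha + cfg.beta + cfg.lam
    d = (
        cfg.alpha * mv[np.ix_(iv, iv)]
        + cfg.beta * mc[np.ix_(ic, ic)]
        + cfg.lam * mj[np.ix_(ij, ij)]
    ) / total
    np.fill_diagonal(d, 0.0)
    return d
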