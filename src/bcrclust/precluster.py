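"""Initial clonal grouping: same V gene, same J gene, same CDR3 length, then
single-linkage splitting at the CDR3 amino-acid identity threshold ``s``.

Sequences whose CDR3 identity chain falls below ``s`` (strictly) end up in
different initial clusters; identity at or above ``s`` links them.  Splitting
uses connected components of the identity graph, the weakest separation
consistent with "separate sequences with less than s% identity" -- the later
refinement stage can only merge, never split, so any over-merge here would be
irreversible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datamodel import AnnotatedSequence, Clustering, ConfigError, Repertoire, strip_allele
from .distances import normalized_levenshtein

logger = logging.getLogger(__name__)


def normalize_threshold(s: float) -> float:
    """Accept a percentage (70) or fraction (0.70); return a fraction."""
    s = float(s)
    if s > 1.0:
        s = s / 100.0
    if not 0.0 < s <= 1.0:
        raise ConfigError(f"identity threshold must be in (0, 1] or (0, 100], got {s}")
    return s


@dataclass(frozen=True)
class PreclusterConfig:
    """Pre-clustering parameters.

    ``s`` is the CDR3 amino-acid identity threshold (default 70%); pairs with
    identity >= s are linked.  ``cdr3_length_tolerance`` > 0 pools V/J groups
    whose CDR3 lengths differ by at most that many residues and switches the
    identity to 1 - normalized Levenshtein (default 0: exact-length groups and
    Hamming identity).
    """

    s: float = 0.70
    allele_level: bool = False
    cdr3_length_tolerance: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", normalize_threshold(self.s))
        if self.cdr3_length_tolerance < 0:
            raise ConfigError("cdr3_length_tolerance must be >= 0")


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of identical positions (Hamming identity) for equal-length
    strings; 1 - normalized Levenshtein otherwise."""
    if len(a) == len(b):
        if not a:
            raise ValueError("empty CDR3")
        return sum(x == y for x, y in zip(a, b)) / len(a)
    return 1.0 - normalized_levenshtein(a, b)


def _group_key(seq: AnnotatedSequence, allele_level: bool) -> Tuple[str, str, int]:
    v = seq.v_gene if allele_level else strip_allele(seq.v_gene)
    j = seq.j_gene if allele_level else strip_allele(seq.j_gene)
    return (v, j, len(seq.cdr3_aa))


def group_by_vj_len(rep: Repertoire, cfg: PreclusterConfig | None = None) -> Clustering:
    """Partition by (V gene, J gene, CDR3 length).

    With a positive length tolerance, groups sharing V and J whose CDR3
    lengths are chained within the tolerance are pooled.
    """
    cfg = cfg or PreclusterConfig()
    groups: Dict[Tuple[str, str, int], List[str]] = {}
    for seq in rep:
        groups.setdefault(_group_key(seq, cfg.allele_level), []).append(seq.seq_id)
    if cfg.cdr3_length_tolerance > 0:
        pooled: Dict[Tuple[str, str, int], List[str]] = {}
        by_vj: Dict[Tuple[str, str], List[int]] = {}
        for (v, j, ln) in groups:
            by_vj.setdefault((v, j), []).append(ln)
        for (v, j), lengths in by_vj.items():
            lengths.sort()
            start = lengths[0]
            members = list(groups[(v, j, start)])
            prev = start
            for ln in lengths[1:]:
                if ln - prev <= cfg.cdr3_length_tolerance:
                    members.extend(groups[(v, j, ln)])
                else:
                    pooled[(v, j, start)] = members
                    start, members = ln, list(groups[(v, j, ln)])
                prev = ln
            pooled[(v, j, start)] = members
        groups = pooled
    return Clustering.from_clusters(
        {f"{v}|{j}|{ln}": members for (v, j, ln), members in groups.items()}
    )


def split_group(
    members: Sequence[AnnotatedSequence], s: float, use_levenshtein: bool = False
) -> List[List[str]]:
    """Single-linkage connected components at identity >= s.

    Members are assumed to share V, J and (within tolerance) CDR3 length.
    Component labels follow input order: each component is reported with its
    members in input order, components ordered by their first member.
    """
    n = len(members)
    if n == 1:
        return [[members[0].seq_id]]
    cdr3s = [m.cdr3_aa for m in members]
    lengths = {len(c) for c in cdr3s}
    if len(lengths) == 1 and not use_levenshtein:
        # vectorized Hamming identity over the equal-length group
        arr = np.frombuffer("".join(cdr3s).encode(), dtype="S1").reshape(n, -1)
        ident = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    else:
        ident = np.ones((n, n))
        for p in range(n):
            for q in range(p + 1, n):
                ident[p, q] = ident[q, p] = cdr3_identity(cdr3s[p], cdr3s[q])
    adj = csr_matrix(ident >= s)
    n_comp, comp = connected_components(adj, directed=False)
    out: List[List[str]] = [[] for _ in range(n_comp)]
    order: List[int] = []
    seen = set()
    for pos, c in enumerate(comp):
        if c not in seen:
            seen.add(c)
            order.append(c)
        out[c].append(members[pos].seq_id)
    return [out[c] for c in order]


def precluster(rep: Repertoire, cfg: PreclusterConfig | None = None) -> Clustering:
    """Full pre-clustering: V/J/length grouping then identity splitting.

    Each resulting cluster is labelled by the seq_id of its first member in
    repertoire order (unique, hence deterministic and stable).
    """
    cfg = cfg or PreclusterConfig()
    if len(rep) == 0:
        logger.warning("pre-clustering an empty repertoire")
        return Clustering({})
    vj_groups = group_by_vj_len(rep, cfg)
    clusters: Dict[str, List[str]] = {}
    for label in vj_groups.labels:
        member_ids = vj_groups.clusters[label]
        members = [rep[i] for i in member_ids]
        use_lev = cfg.cdr3_length_tolerance > 0
        for component in split_group(members, cfg.s, use_levenshtein=use_lev):
            clusters[component[0]] = component
    result = Clustering.from_clusters(clusters)
    logger.info("pre-clustering: %d sequences -> %d initial clusters", len(rep), result.n_clusters)
    return result
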