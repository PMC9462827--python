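"""Read/write AIRR rearrangement tables and FASTA; emit clustering results.

Input tables follow the MiAIRR column names (``sequence_id``, ``v_call``,
``j_call``, ``junction_aa``; ``cdr3_aa`` is accepted as an alternative CDR3
column).  Rows lacking a V call, J call or CDR3 are dropped and counted, the
way repertoires with partial V(D)J annotation are normally handled.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .datamodel import (
    AA_ALPHABET,
    AnnotatedSequence,
    Clustering,
    ConsistencyError,
    FormatError,
    Repertoire,
    strip_allele,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call")
CDR3_COLUMNS = ("cdr3_aa", "junction_aa")
TRUTHY = {"t", "true", "1", "yes", "y"}


def _first_call(value: str) -> str:
    """Keep the first listed call of a multi-allele annotation."""
    return value.split(",")[0].strip()


def _clean(value) -> str:
    """Cell content as a stripped string; missing values become ''."""
    if value is None or (isinstance(value, float) and value != value):
        return ""
    return str(value).strip()


def repertoire_from_frame(
    df: pd.DataFrame,
    name: str = "repertoire",
    column_map: Optional[Dict[str, str]] = None,
    cdr3_column: Optional[str] = None,
) -> Repertoire:
    """Build a :class:`Repertoire` from an AIRR-style DataFrame.

    ``column_map`` renames non-standard columns to AIRR names before parsing;
    ``cdr3_column`` forces a specific CDR3 source column (default: ``cdr3_aa``
    if present, else ``junction_aa``).
    """
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if cdr3_column is not None:
        if cdr3_column not in df.columns:
            raise FormatError(f"missing required column {cdr3_column!r}")
        cdr3_col = cdr3_column
    else:
        cdr3_col = next((c for c in CDR3_COLUMNS if c in df.columns), None)
        if cdr3_col is None:
            raise FormatError(
                f"missing CDR3 column: expected one of {list(CDR3_COLUMNS)}"
            )
    if len(df) == 0:
        logger.warning("AIRR table %s has no rows", name)
        return Repertoire([], name=name)

    ids = df["sequence_id"].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ConsistencyError(f"duplicated sequence_id values: {dup[:10]}")

    sequences: List[AnnotatedSequence] = []
    dropped = 0
    for rec in df.to_dict(orient="records"):
        v = _clean(rec.get("v_call"))
        j = _clean(rec.get("j_call"))
        cdr3 = _clean(rec.get(cdr3_col)).upper()
        if not v or not j or not cdr3:
            dropped += 1
            continue
        if set(cdr3) - AA_ALPHABET:
            dropped += 1
            continue
        nt = _clean(rec.get("sequence")).upper() or None
        try:
            count = max(1, int(float(_clean(rec.get("duplicate_count")) or 1)))
        except ValueError:
            count = 1
        productive = (_clean(rec.get("productive")) or "T").lower() in TRUTHY
        sequences.append(
            AnnotatedSequence(
                seq_id=str(rec["sequence_id"]),
                v_gene=_first_call(v),
                j_gene=_first_call(j),
                cdr3_aa=cdr3,
                nt_sequence=nt,
                duplicate_count=count,
                productive=productive,
            )
        )
    logger.info("%s: kept %d sequences, dropped %d without full annotation",
                name, len(sequences), dropped)
    rep = Repertoire(sequences, name=name)
    rep.n_dropped = dropped  # type: ignore[attr-defined]
    return rep


def read_airr(
    path,
    column_map: Optional[Dict[str, str]] = None,
    cdr3_column: Optional[str] = None,
) -> Repertoire:
    """Read an AIRR rearrangement TSV into a :class:`Repertoire`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty input file") from exc
    return repertoire_from_frame(df, name=path.stem, column_map=column_map,
                                 cdr3_column=cdr3_column)


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA records as (id, upper-cased sequence) pairs."""
    from Bio import SeqIO

    records: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def clone_id_map(rep: Repertoire, clustering: Clustering) -> Dict[str, str]:
    """Numeric clone ids ("1", "2", ...) ordered by decreasing read abundance
    (ties broken by cluster label)."""
    reads = {
        label: sum(rep[m].duplicate_count for m in members)
        for label, members in clustering.clusters.items()
    }
    ranked = sorted(reads, key=lambda l: (-reads[l], l))
    renum = {label: str(rank + 1) for rank, label in enumerate(ranked)}
    return {seq_id: renum[label] for seq_id, label in clustering.assignment.items()}


def write_clustering(
    rep: Repertoire,
    clustering: Clustering,
    path,
    summary_path=None,
    dcfg=None,
) -> None:
    """Write the AIRR table augmented with a ``clone_id`` column, plus a
    per-cluster summary TSV (label, sizes, abundance, representative V/J,
    uniformity)."""
    from collections import Counter

    from .distances import DistanceConfig
    from .refine import uniformity

    for seq_id in clustering.assignment:
        if seq_id not in rep:
            raise ConsistencyError(f"clustered id {seq_id!r} absent from repertoire")
    clustering.check_partition(rep.ids)
    assert sum(clustering.sizes().values()) == len(rep)

    path = Path(path)
    clone_ids = clone_id_map(rep, clustering)
    df = rep.to_frame()
    df["clone_id"] = [clone_ids.get(i, "") for i in df["sequence_id"]]
    df.to_csv(path, sep="\t", index=False)

    if summary_path is None:
        summary_path = path.with_name(path.stem + "_clusters.tsv")
    dcfg = dcfg or DistanceConfig()
    total_reads = rep.n_reads
    rows = []
    by_clone: Dict[str, List[str]] = {}
    for seq_id, cid in clone_ids.items():
        by_clone.setdefault(cid, []).append(seq_id)
    for cid in sorted(by_clone, key=int):
        members = by_clone[cid]
        reads = sum(rep[m].duplicate_count for m in members)
        v_rep = Counter(strip_allele(rep[m].v_gene) for m in members).most_common()
        j_rep = Counter(strip_allele(rep[m].j_gene) for m in members).most_common()
        rows.append(
            {
                "clone_id": cid,
                "n_sequences": len(members),
                "n_reads": reads,
                "abundance": reads / total_reads if total_reads else 0.0,
                "v_gene": min(v for v, c in v_rep if c == v_rep[0][1]),
                "j_gene": min(j for j, c in j_rep if c == j_rep[0][1]),
                "uniformity": uniformity(rep, members, dcfg),
            }
        )
    pd.DataFrame(
        rows,
        columns=["clone_id", "n_sequences", "n_reads", "abundance",
                 "v_gene", "j_gene", "uniformity"],
    ).to_csv(summary_path, sep="\t", index=False)
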