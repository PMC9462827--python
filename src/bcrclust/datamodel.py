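"""Core containers for annotated IGH repertoires and clonal-lineage partitions.

A repertoire is an ordered collection of heavy-chain sequences, each carrying
the germline V and J gene calls and the CDR3 (or junction) amino-acid string
produced by an upstream V(D)J annotation tool.  A clustering is a partition of
the repertoire's sequence identifiers into clonal lineages.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
NT_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file or table (missing column, bad record...)."""


class ConsistencyError(ValueError):
    """Two objects that must agree (e.g. id sets of clustering vs repertoire) do not."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class SimulationError(RuntimeError):
    """Repertoire simulation could not satisfy its constraints."""


def strip_allele(label: str) -> str:
    """Drop the ``*NN`` allele suffix of a gene call: ``IGHV1-69*01`` -> ``IGHV1-69``."""
    return label.split("*", 1)[0]


@dataclass(frozen=True)
class AnnotatedSequence:
    """One IGH read/clonotype with its germline annotation.

    Parameters
    ----------
    seq_id : opaque unique identifier.
    v_gene, j_gene : germline gene calls; an allele suffix (``*01``) may be present.
    cdr3_aa : CDR3 (or junction) amino-acid sequence, uppercase.
    nt_sequence : optional full nucleotide sequence.
    duplicate_count : number of reads collapsed into this record (>= 1).
    productive : whether the rearrangement translates without a stop codon.
    """

    seq_id: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    nt_sequence: Optional[str] = None
    duplicate_count: int = 1
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.v_gene or not self.j_gene:
            raise ValueError(f"{self.seq_id}: v_gene and j_gene must be non-empty")
        if not self.cdr3_aa:
            raise ValueError(f"{self.seq_id}: cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.seq_id}: cdr3_aa contains invalid residues {sorted(bad)!r}"
            )
        if self.duplicate_count < 1:
            raise ValueError(f"{self.seq_id}: duplicate_count must be >= 1")

    @property
    def clonotype_key(self) -> Tuple[str, str, str, Optional[str]]:
        return (self.v_gene, self.j_gene, self.cdr3_aa, self.nt_sequence)


class Repertoire:
    """Ordered collection of :class:`AnnotatedSequence` with unique identifiers."""

    def __init__(self, sequences: Iterable[AnnotatedSequence], name: str = "repertoire"):
        self.sequences = list(sequences)
        self.name = name
        self._index: Dict[str, int] = {}
        for pos, seq in enumerate(self.sequences):
            if seq.seq_id in self._index:
                raise ConsistencyError(f"duplicated sequence_id: {seq.seq_id!r}")
            self._index[seq.seq_id] = pos

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AnnotatedSequence]:
        return iter(self.sequences)

    def __getitem__(self, seq_id: str) -> AnnotatedSequence:
        return self.sequences[self._index[seq_id]]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def position(self, seq_id: str) -> int:
        return self._index[seq_id]

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(s.seq_id for s in self.sequences)

    @property
    def n_reads(self) -> int:
        return sum(s.duplicate_count for s in self.sequences)

    def to_frame(self) -> pd.DataFrame:
        """AIRR-style rearrangement table (tab-separated on write)."""
        return pd.DataFrame(
            {
                "sequence_id": [s.seq_id for s in self.sequences],
                "v_call": [s.v_gene for s in self.sequences],
                "j_call": [s.j_gene for s in self.sequences],
                "junction_aa": [s.cdr3_aa for s in self.sequences],
                "sequence": [s.nt_sequence or "" for s in self.sequences],
                "duplicate_count": [s.duplicate_count for s in self.sequences],
                "productive": ["T" if s.productive else "F" for s in self.sequences],
            }
        )


class Clustering:
    """A partition of sequence identifiers into labelled clonal lineages.

    The assignment is a total function on the clustered ids; labels are plain
    strings, stable under serialization.  Member order within a cluster follows
    insertion order of the assignment.
    """

    def __init__(self, assignment: Mapping[str, str]):
        self.assignment: Dict[str, str] = {str(k): str(v) for k, v in assignment.items()}
        clusters: Dict[str, list] = {}
        for seq_id, label in self.assignment.items():
            clusters.setdefault(label, []).append(seq_id)
        self._clusters: Dict[str, Tuple[str, ...]] = {
            label: tuple(members) for label, members in clusters.items()
        }

    @classmethod
    def from_clusters(cls, clusters: Mapping[str, Iterable[str]]) -> "Clustering":
        assignment: Dict[str, str] = {}
        for label, members in clusters.items():
            members = list(members)
            if not members:
                raise ConsistencyError(f"empty cluster {label!r}")
            for seq_id in members:
                if seq_id in assignment:
                    raise ConsistencyError(
                        f"sequence {seq_id!r} assigned to both "
                        f"{assignment[seq_id]!r} and {label!r}"
                    )
                assignment[seq_id] = str(label)
        return cls(assignment)

    @property
    def clusters(self) -> Dict[str, Tuple[str, ...]]:
        return self._clusters

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(sorted(self._clusters))

    @property
    def n_clusters(self) -> int:
        return len(self._clusters)

    def __len__(self) -> int:
        return len(self.assignment)

    def sizes(self) -> Dict[str, int]:
        return {label: len(m) for label, m in self._clusters.items()}

    def check_partition(self, ids: Iterable[str]) -> None:
        """Raise :class:`ConsistencyError` unless this is a partition of *ids*."""
        want = set(ids)
        have = set(self.assignment)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ConsistencyError(
                f"clustering does not cover the id set: missing={missing[:10]}"
                f"{'...' if len(missing) > 10 else ''}, extra={extra[:10]}"
                f"{'...' if len(extra) > 10 else ''}"
            )

    def same_partition(self, other: "Clustering") -> bool:
        """True if both objects induce the same partition (labels ignored)."""
        mine = {frozenset(m) for m in self._clusters.values()}
        theirs = {frozenset(m) for m in other._clusters.values()}
        return mine == theirs
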