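"""Benchmark simulator: V(D)J recombination, Galton-Watson lineage growth with
context-biased somatic hypermutation, and assembly into truth-labelled
monoclonal / oligoclonal / polyclonal repertoires.

Each lineage starts from a naive ancestor built by joining a random V, D and
J segment with exonuclease trimming (0-5 nt per junction side) and random N
insertions (0-10 nt per junction).  The lineage then grows as a branching
process in which every node draws Poisson(lambda) offspring, and every
offspring acquires m ~ Poisson(mu0 * lambda0) point substitutions, where mu0
is the parent sequence's mean per-site mutability.  Mutability follows the
classic AID hotspot bias: positions at the centre of WRC / GYW motifs mutate
``hotspot_weight`` times faster than baseline; an S5F-style 5-mer table can
be loaded instead.  Only productive descendants (no stop codon in the V
reading frame) are kept.

The bundled germline pool is SYNTHETIC: segments are random in-frame coding
sequences generated deterministically in code, with the conserved CDR3
anchors (V-end cysteine, J-frame tryptophan) placed by construction.  It
exists so that benchmarks need no external database; user-supplied V/D/J
FASTA files are accepted wherever a pool is taken.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    AnnotatedSequence,
    Clustering,
    ConfigError,
    Repertoire,
    SimulationError,
)

REPERTOIRE_TYPES = ("monoclonal", "oligoclonal", "polyclonal")

# default lineage counts per repertoire type, matching typical benchmark sizes
DEFAULT_N_LINEAGES = {"monoclonal": 34, "oligoclonal": 43, "polyclonal": 44}

_CODON_TABLE = {}
_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_AA3 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate in frame 0; trailing partial codon ignored."""
    return "".join(_AA3[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


def is_productive(nt: str) -> bool:
    return "*" not in translate(nt)


@dataclass(frozen=True)
class GermlinePool:
    """Named V, D and J germline segments (nucleotides).

    V segments are in frame 0 and end with the conserved cysteine codon six
    nucleotides before their 3' end; J segments are ``head + TGG + tail`` with
    ``len(head) = 9`` and an in-frame tail, so that any in-frame junction
    leaves the tryptophan codon in frame.
    """

    v: Dict[str, str]
    d: Dict[str, str]
    j: Dict[str, str]
    j_head_len: int = 9

    def __post_init__(self) -> None:
        if not self.v or not self.d or not self.j:
            raise ConfigError("germline pools must be non-empty")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """Random stop-free codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def synthetic_germline_pool(
    n_v: int = 20, n_d: int = 8, n_j: int = 6, seed: int = 104729
) -> GermlinePool:
    """Deterministic synthetic germline set (see module docstring)."""
    rng = np.random.default_rng(seed)
    v = {}
    for i in range(n_v):
        name = f"IGHV{i % 7 + 1}-{i // 7 + 1}*01"
        # 55 leading codons + conserved Cys + 2 tail codons = 58 codons
        v[name] = _random_codons(rng, 55) + ("TGT" if i % 2 else "TGC") + _random_codons(rng, 2)
    d = {
        f"IGHD{i + 1}-1*01": "".join(rng.choice(list(_BASES), size=int(rng.integers(12, 22))))
        for i in range(n_d)
    }
    j = {}
    for i in range(n_j):
        head = "".join(rng.choice(list(_BASES), size=9))
        tail = _random_codons(rng, 6)
        j[f"IGHJ{i + 1}*01"] = head + "TGG" + tail
    return GermlinePool(v=v, d=d, j=j, j_head_len=9)


def load_germline_fasta(v_path, d_path, j_path, j_head_len: int = 9) -> GermlinePool:
    """Build a pool from user V/D/J FASTA files (same anchor conventions)."""
    from .io_airr import read_fasta

    return GermlinePool(
        v=dict(read_fasta(v_path)),
        d=dict(read_fasta(d_path)),
        j=dict(read_fasta(j_path)),
        j_head_len=j_head_len,
    )


# ---------------------------------------------------------------------------
# mutability models
# ---------------------------------------------------------------------------

class HotspotModel:
    """WRC / GYW hotspot mutability: motif centres get ``hot_weight``,
    everything else baseline 1.0.  Positions whose context is truncated at a
    sequence edge cannot match a motif and stay at baseline."""

    def __init__(self, hot_weight: float = 5.0):
        if hot_weight <= 0:
            raise ConfigError("hot_weight must be positive")
        self.hot_weight = float(hot_weight)

    def mutabilities(self, seq: str) -> np.ndarray:
        mu = np.ones(len(seq))
        w = self.hot_weight
        for i, base in enumerate(seq):
            if base == "C" and i >= 2 and seq[i - 2] in "AT" and seq[i - 1] in "AG":
                mu[i] = w  # WRC, C is the mutating centre
            elif base == "G" and i + 2 < len(seq) and seq[i + 1] in "CT" and seq[i + 2] in "AT":
                mu[i] = w  # GYW, reverse-complement motif
        return mu


class S5FModel:
    """5-mer context mutability loaded from a table; unknown or truncated
    contexts fall back to 1.0."""

    def __init__(self, table: Dict[str, float]):
        self.table = {k.upper(): float(v) for k, v in table.items()}

    @classmethod
    def from_csv(cls, path) -> "S5FModel":
        import csv

        table: Dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if len(row) >= 2 and len(row[0].strip()) == 5:
                    try:
                        table[row[0].strip()] = float(row[1])
                    except ValueError:
                        continue  # header row
        if not table:
            raise ConfigError(f"{path}: no 5-mer rows found")
        return cls(table)

    def mutabilities(self, seq: str) -> np.ndarray:
        mu = np.ones(len(seq))
        for i in range(2, len(seq) - 2):
            mu[i] = self.table.get(seq[i - 2:i + 3], 1.0)
        return mu


def site_mutabilities(seq: str, model=None) -> Tuple[np.ndarray, float]:
    """Per-site mutabilities mu_i and their mean mu0 for a nucleotide sequence."""
    if len(seq) < 5:
        raise ValueError("sequence must be at least 5 nt (5-mer context)")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)!r}")
    model = model or HotspotModel()
    mu = model.mutabilities(seq)
    return mu, float(mu.mean())


# ---------------------------------------------------------------------------
# recombination and lineage growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ancestor:
    """A naive (unmutated) recombined sequence with its CDR3 anchors."""

    nt: str
    v_name: str
    d_name: str
    j_name: str
    cys_start: int  # nt index of the conserved Cys codon (frame 0)
    trp_end: int    # nt index one past the conserved Trp codon

    def cdr3_aa(self, nt: Optional[str] = None) -> str:
        """Junction amino acids, conserved Cys through Trp inclusive."""
        return translate((nt or self.nt)[self.cys_start:self.trp_end])


@dataclass
class SimConfig:
    """Simulation parameters.

    ``branching_lambda`` is the Poisson offspring rate (default 2);
    ``lambda0`` the baseline mutation-load rate (default 0.26; the benchmark
    grid uses {0.16, 0.26, 0.36, 0.46}).  ``target_size`` is the approximate
    repertoire size before productive-only filtering; realized repertoires can
    be smaller.  ``tree_cap`` bounds each lineage tree's node count.
    """

    branching_lambda: float = 2.0
    lambda0: float = 0.26
    repertoire_type: str = "polyclonal"
    n_lineages: Optional[int] = None
    target_size: int = 1000
    seed: int = 0
    tree_cap: int = 500
    hotspot_weight: float = 5.0
    n_insert_max: int = 10
    trim_max: int = 5
    min_lineage_size: int = 2
    retry_budget: int = 50

    def __post_init__(self) -> None:
        if self.branching_lambda <= 0 or self.lambda0 <= 0:
            raise ConfigError("branching_lambda and lambda0 must be positive")
        if self.repertoire_type not in REPERTOIRE_TYPES:
            raise ConfigError(f"repertoire_type must be one of {REPERTOIRE_TYPES}")
        if self.n_lineages is None:
            self.n_lineages = DEFAULT_N_LINEAGES[self.repertoire_type]
        if self.n_lineages < 1:
            raise ConfigError("n_lineages must be >= 1")
        if self.target_size < self.n_lineages:
            raise ConfigError("target_size must be >= n_lineages")

    def to_dict(self) -> Dict[str, object]:
        return {
            "branching_lambda": self.branching_lambda,
            "lambda0": self.lambda0,
            "repertoire_type": self.repertoire_type,
            "n_lineages": self.n_lineages,
            "target_size": self.target_size,
            "seed": self.seed,
            "tree_cap": self.tree_cap,
            "hotspot_weight": self.hotspot_weight,
        }


@dataclass
class SimTruth:
    """A simulated repertoire with its ground-truth lineage partition."""

    repertoire: Repertoire
    truth: Clustering
    trees: Dict[str, Dict[str, Optional[str]]]  # lineage -> node -> parent
    ancestors: Dict[str, Ancestor]
    params: SimConfig

    def write(self, outdir) -> None:
        """Write AIRR TSV, truth labels, FASTA, per-lineage edge lists and a
        parameter manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.repertoire.to_frame()
        df.to_csv(outdir / "repertoire.tsv", sep="\t", index=False)
        truth_df = df[["sequence_id"]].copy()
        truth_df["clone_id"] = [self.truth.assignment[i] for i in truth_df["sequence_id"]]
        truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "repertoire.fasta", "w") as fh:
            for seq in self.repertoire:
                fh.write(f">{seq.seq_id}\n{seq.nt_sequence}\n")
        with open(outdir / "trees.tsv", "w") as fh:
            fh.write("lineage\tchild\tparent\n")
            for lineage, parents in self.trees.items():
                for child, parent in parents.items():
                    fh.write(f"{lineage}\t{child}\t{parent or ''}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.params.to_dict(), fh, indent=2)


def recombine_ancestor(
    pool: GermlinePool, rng: np.random.Generator, cfg: Optional[SimConfig] = None
) -> Ancestor:
    """Draw one productive naive ancestor: random V/D/J picks, 0-``trim_max``
    nt trimmed per junction side, 0-``n_insert_max`` random N nucleotides per
    junction, rejected until in frame and stop-free."""
    cfg = cfg or SimConfig()
    bases = list(_BASES)
    for _ in range(cfg.retry_budget * 20):
        v_name = str(rng.choice(sorted(pool.v)))
        d_name = str(rng.choice(sorted(pool.d)))
        j_name = str(rng.choice(sorted(pool.j)))
        v_seq, d_seq, j_seq = pool.v[v_name], pool.d[d_name], pool.j[j_name]
        tv = int(rng.integers(0, cfg.trim_max + 1))
        td5 = int(rng.integers(0, cfg.trim_max + 1))
        td3 = int(rng.integers(0, cfg.trim_max + 1))
        tj = int(rng.integers(0, min(cfg.trim_max, pool.j_head_len) + 1))
        n1 = "".join(rng.choice(bases, size=int(rng.integers(0, cfg.n_insert_max + 1))))
        n2 = "".join(rng.choice(bases, size=int(rng.integers(0, cfg.n_insert_max + 1))))
        d_core = d_seq[td5:len(d_seq) - td3]
        nt = v_seq[:len(v_seq) - tv] + n1 + d_core + n2 + j_seq[tj:]
        if len(nt) % 3 != 0:
            continue
        cys_start = len(v_seq) - 9  # Cys codon sits 9 nt before the V 3' end
        tail_len = len(j_seq) - pool.j_head_len - 3  # nt after the Trp codon
        trp_end = len(nt) - tail_len
        if is_productive(nt):
            return Ancestor(nt, v_name, d_name, j_name, cys_start, trp_end)
    raise SimulationError(
        "could not draw a productive in-frame ancestor within the retry budget"
    )


def mutate(
    seq: str, lambda0: float, rng: np.random.Generator, model=None
) -> str:
    """One round of SHM: m ~ Poisson(mu0 * lambda0) substitutions at positions
    drawn proportionally to the per-site mutability, each to a uniform
    alternative base."""
    mu, mu0 = site_mutabilities(seq, model)
    m = int(rng.poisson(mu0 * lambda0))
    if m == 0:
        return seq
    m = min(m, len(seq))
    positions = rng.choice(len(seq), size=m, replace=False, p=mu / mu.sum())
    out = list(seq)
    for pos in positions:
        out[pos] = str(rng.choice([b for b in _BASES if b != out[pos]]))
    return "".join(out)


def simulate_lineage(
    ancestor: Ancestor,
    cfg: SimConfig,
    rng: np.random.Generator,
    model=None,
) -> Tuple[Dict[str, str], Dict[str, Optional[str]], List[str]]:
    """Grow one Galton-Watson lineage from the ancestor.

    Returns ``(sequences, parent_map, productive_ids)``.  The tree is grown
    breadth-first, capped at ``tree_cap`` nodes; node ids are ``n0`` (root),
    ``n1``, ... in creation order.  All nodes (internal and leaf) are
    candidate repertoire members; only stop-free ones are listed productive.
    """
    model = model or HotspotModel(cfg.hotspot_weight)
    sequences: Dict[str, str] = {"n0": ancestor.nt}
    parents: Dict[str, Optional[str]] = {"n0": None}
    queue = ["n0"]
    counter = 1
    while queue and counter < cfg.tree_cap:
        node = queue.pop(0)
        n_offspring = int(rng.poisson(cfg.branching_lambda))
        for _ in range(n_offspring):
            if counter >= cfg.tree_cap:
                break
            child = f"n{counter}"
            counter += 1
            sequences[child] = mutate(sequences[node], cfg.lambda0, rng, model)
            parents[child] = node
            queue.append(child)
    productive = [nid for nid in sequences if is_productive(sequences[nid])]
    return sequences, parents, productive


def _size_targets(cfg: SimConfig) -> List[int]:
    """Per-lineage sampling targets implementing the clonality profiles:
    monoclonal: one lineage ~72% of the target (>= 70% after realization);
    oligoclonal: two dominant lineages at ~14% and ~9%; polyclonal: even
    sizes, each necessarily <= 5%."""
    n, t = cfg.n_lineages, cfg.target_size
    lo = cfg.min_lineage_size
    if cfg.repertoire_type == "monoclonal":
        if n < 2:
            raise ConfigError("monoclonal repertoires need >= 2 lineages")
        top = round(0.72 * t)
        rest = t - top
        base, extra = divmod(rest, n - 1)
        sizes = [top] + [max(lo, base + (1 if i < extra else 0)) for i in range(n - 1)]
    elif cfg.repertoire_type == "oligoclonal":
        if n < 3:
            raise ConfigError("oligoclonal repertoires need >= 3 lineages")
        s1, s2 = round(0.14 * t), round(0.09 * t)
        rest = t - s1 - s2
        base, extra = divmod(rest, n - 2)
        sizes = [s1, s2] + [max(lo, base + (1 if i < extra else 0)) for i in range(n - 2)]
    else:
        base, extra = divmod(t, n)
        sizes = [max(lo, base + (1 if i < extra else 0)) for i in range(n)]
        if max(sizes) / t > 0.05:
            raise ConfigError(
                f"polyclonal profile infeasible: {n} lineages of target {t} "
                "would exceed the 5% cap"
            )
    return sizes


def assemble_repertoire(
    cfg: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    pool: Optional[GermlinePool] = None,
) -> SimTruth:
    """Simulate independent lineages and assemble them into one repertoire
    matching the configured clonality profile.

    Lineages are subsampled (without replacement) from their productive nodes
    to the per-lineage targets.  A monoclonal dominant lineage whose tree cap
    yields fewer productive sequences than its target keeps all of them, and
    the minor lineages are scaled down to preserve the >= 70% dominance; the
    realized repertoire is then smaller than the nominal target.
    """
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pool = pool or synthetic_germline_pool()
    model = HotspotModel(cfg.hotspot_weight)
    targets = _size_targets(cfg)

    sequences: List[AnnotatedSequence] = []
    assignment: Dict[str, str] = {}
    trees: Dict[str, Dict[str, Optional[str]]] = {}
    ancestors: Dict[str, Ancestor] = {}
    scale = 1.0
    for li, target in enumerate(targets):
        label = f"L{li:03d}"
        want = target if li == 0 else max(cfg.min_lineage_size, round(target * scale))
        realized = None
        for _ in range(cfg.retry_budget):
            ancestor = recombine_ancestor(pool, rng, cfg)
            seqs, parents, productive = simulate_lineage(ancestor, cfg, rng, model)
            if len(productive) >= min(want, cfg.min_lineage_size):
                realized = (ancestor, seqs, parents, productive)
                if len(productive) >= want or len(productive) >= cfg.tree_cap * 0.8:
                    break
        if realized is None:
            raise SimulationError(f"lineage {label}: no viable tree in retry budget")
        ancestor, seqs, parents, productive = realized
        take = min(want, len(productive))
        if li == 0 and cfg.repertoire_type == "monoclonal" and take < target:
            scale = take / target  # shrink minor lineages to keep dominance
        chosen = sorted(
            rng.choice(np.array(productive, dtype=object), size=take, replace=False)
        )
        trees[label] = parents
        ancestors[label] = ancestor
        for node in chosen:
            seq_id = f"{label}_{node}"
            nt = seqs[node]
            sequences.append(
                AnnotatedSequence(
                    seq_id=seq_id,
                    v_gene=ancestor.v_name,
                    j_gene=ancestor.j_name,
                    cdr3_aa=ancestor.cdr3_aa(nt),
                    nt_sequence=nt,
                    duplicate_count=1,
                    productive=True,
                )
            )
            assignment[seq_id] = label
    rep = Repertoire(sequences, name=f"sim_{cfg.repertoire_type}_l0{cfg.lambda0}")
    truth = Clustering(assignment)
    truth.check_partition(rep.ids)
    return SimTruth(rep, truth, trees, ancestors, cfg)
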