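import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bcrclust.datamodel import AnnotatedSequence, Repertoire

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_seq(i, v="IGHV1-69*01", j="IGHJ4*01", cdr3="CARDYW", nt=None, count=1):
    return AnnotatedSequence(f"s{i}", v, j, cdr3, nt_sequence=nt, duplicate_count=count)


def make_repertoire(cdr3s, v="IGHV1-69*01", j="IGHJ4*01"):
    """One sequence per CDR3, shared V/J, ids s0, s1, ..."""
    return Repertoire([make_seq(i, v=v, j=j, cdr3=c) for i, c in enumerate(cdr3s)])


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture
def lev_oracle():
    return dp_levenshtein


@pytest.fixture
def three_lineage_repertoire():
    """Three well-separated lineages: distinct V genes and CDR3s with
    between-lineage identity < 0.3, within-lineage identity > 0.8."""
    specs = [
        ("IGHV1-2*01", "IGHJ4*01", ["CARDYWGQGTW", "CARDYWGQGTW", "CARDYWGQGSW", "CARDYWGQGAW"]),
        ("IGHV3-7*01", "IGHJ6*01", ["CTKFSPNHEIW", "CTKFSPNHEIW", "CTKFSPNHELW"]),
        ("IGHV5-9*01", "IGHJ1*01", ["CMQNRGLVDPW", "CMQNRGLVDAW", "CMQNRGLVDPW"]),
    ]
    seqs, truth = [], {}
    k = 0
    for li, (v, j, cdr3s) in enumerate(specs):
        for c in cdr3s:
            seqs.append(AnnotatedSequence(f"s{k}", v, j, c))
            truth[f"s{k}"] = f"T{li}"
            k += 1
    from bcrclust.datamodel import Clustering

    return Repertoire(seqs), Clustering(truth)
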