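"""Refinement-stage tests.

Distance-driven cases use either real sequences under a CDR3-only composed
distance (alpha=0, beta=1, lam=0 makes d equal the normalized Levenshtein of
the CDR3s) or a hand-crafted distance matrix passed straight to the engine,
which allows geometries a string metric cannot realize.
"""
import numpy as np
import pytest

from bcrclust.datamodel import Clustering, Repertoire
from bcrclust.distances import DistanceConfig
from bcrclust.refine import (
    RefineConfig,
    avg_density,
    cluster_repertoire,
    inter_distance,
    intra_distance,
    local_density,
    merge_singletons,
    refine,
    uniformity,
)
from conftest import make_repertoire, make_seq

CDR3_ONLY = DistanceConfig(alpha=0.0, beta=1.0, lam=0.0)


def crafted(rep_size, entries):
    """Symmetric distance matrix from {(i, j): d} entries (rest 0)."""
    mat = np.zeros((rep_size, rep_size))
    for (i, j), d in entries.items():
        mat[i, j] = mat[j, i] = d
    return mat


def dummy_rep(n):
    return Repertoire([make_seq(i) for i in range(n)])


class TestSilhouetteTerms:
    def test_intra_distance_is_the_mean(self):
        # d(i,j)=0.2 and d(i,m)=0.4 via CDR3 Levenshtein on length-5 strings
        rep = make_repertoire(["AAAAA", "AAAAC", "AAACC"])
        a_i = intra_distance(rep, "s0", ["s0", "s1", "s2"], CDR3_ONLY)
        assert a_i == pytest.approx(0.3)

    def test_intra_distance_zero_for_identical_clonotypes(self):
        rep = make_repertoire(["CARDYW", "CARDYW"])
        assert intra_distance(rep, "s0", ["s0", "s1"], CDR3_ONLY) == 0.0

    def test_intra_undefined_for_singleton(self):
        rep = make_repertoire(["CARDYW"])
        with pytest.raises(ValueError):
            intra_distance(rep, "s0", ["s0"], CDR3_ONLY)

    def test_inter_distance_picks_smallest_mean(self):
        # cluster L1 at mean 0.6 from s0, cluster L2 at mean 0.4
        rep = make_repertoire(["AAAAA", "AACCC", "AAACC", "AAAAC"])
        cl = Clustering.from_clusters({"me": ["s0"], "L1": ["s1"], "L2": ["s2", "s3"]})
        b_i, nearest = inter_distance(rep, "s0", cl, CDR3_ONLY)
        assert b_i == pytest.approx(0.3)  # mean(0.4, 0.2)
        assert nearest == "L2"

    def test_inter_distance_averages_not_min_of_min(self):
        # duplicate of s0 plus a maximally distant member: b_i = (0 + 1)/2
        rep = make_repertoire(["AAAAA", "AAAAA", "CCCCC"])
        cl = Clustering.from_clusters({"me": ["s0"], "other": ["s1", "s2"]})
        b_i, _ = inter_distance(rep, "s0", cl, CDR3_ONLY)
        assert b_i == pytest.approx(0.5)


class TestRefine:
    def test_single_cluster_returned_unchanged(self):
        rep = make_repertoire(["AAAAA", "CCCCC"])
        cl = Clustering.from_clusters({"k": ["s0", "s1"]})
        assert refine(rep, cl, CDR3_ONLY).same_partition(cl)

    def test_loose_clusters_with_close_neighbours_merge(self):
        rep = dummy_rep(4)
        # within-cluster 0.9, cross 0.1: every a_i > b_i
        dist = crafted(4, {(0, 1): 0.9, (2, 3): 0.9,
                           (0, 2): 0.1, (0, 3): 0.1, (1, 2): 0.1, (1, 3): 0.1})
        cl = Clustering.from_clusters({"k": ["s0", "s1"], "l": ["s2", "s3"]})
        out = refine(rep, cl, dist=dist)
        assert out.n_clusters == 1

    def test_tight_separated_clusters_untouched(self):
        rep = dummy_rep(4)
        dist = crafted(4, {(0, 1): 0.05, (2, 3): 0.05,
                           (0, 2): 0.9, (0, 3): 0.9, (1, 2): 0.9, (1, 3): 0.9})
        cl = Clustering.from_clusters({"k": ["s0", "s1"], "l": ["s2", "s3"]})
        assert refine(rep, cl, dist=dist).same_partition(cl)

    def test_recovers_three_lineages_end_to_end(self, three_lineage_repertoire):
        rep, truth = three_lineage_repertoire
        clustering, report = cluster_repertoire(rep)
        assert clustering.same_partition(truth)
        assert report["n_clusters_final"] == 3

    def test_two_identical_clonotypes_one_cluster(self):
        rep = make_repertoire(["CARDYW", "CARDYW"])
        clustering, _ = cluster_repertoire(rep)
        assert clustering.n_clusters == 1

    def test_disabled_stages_reproduce_precluster(self):
        from bcrclust.precluster import precluster

        rep = make_repertoire(["AAAAAA", "AAAAAC", "CCCCCC", "CARDYW"])
        rcfg = RefineConfig(refinement=False, merge_singletons=False)
        clustering, _ = cluster_repertoire(rep, rcfg=rcfg)
        assert clustering.same_partition(precluster(rep))

    def test_determinism(self):
        rng = np.random.default_rng(0)
        n = 40
        rep = dummy_rep(n)
        dist = rng.uniform(0.0, 1.0, size=(n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = rng.integers(0, 8, size=n)
        cl = Clustering({f"s{i}": f"c{labels[i]}" for i in range(n)})
        first = refine(rep, cl, dist=dist)
        second = refine(rep, cl, dist=dist)
        assert first.assignment == second.assignment


class TestDensityAndUniformity:
    def test_local_density_is_min(self):
        rep = make_repertoire(["AAAAAAAAAA", "AAAAAAACCC", "CCCCCAAAAA"])
        # s0-s1: 0.3, s0-s2: 0.5
        assert local_density(rep, "s0", ["s0", "s1", "s2"], CDR3_ONLY) == pytest.approx(0.3)

    def test_local_density_zero_with_duplicate(self):
        rep = make_repertoire(["CARDYW", "CARDYW", "CAAAFW"])
        assert local_density(rep, "s0", ["s0", "s1", "s2"], CDR3_ONLY) == 0.0

    def test_avg_density_is_mean_of_local(self):
        rep = make_repertoire(["AAAAAAAAAA", "AAAAAAAACC", "CCCAAAAACC"])
        # locals: s0: 0.2, s1: 0.2, s2: 0.3
        members = ["s0", "s1", "s2"]
        locals_ = [local_density(rep, m, members, CDR3_ONLY) for m in members]
        assert avg_density(rep, members, CDR3_ONLY) == pytest.approx(np.mean(locals_))
        assert locals_ == pytest.approx([0.2, 0.2, 0.3])

    def test_uniformity_singleton_and_uniform_cluster_are_zero(self):
        rep = make_repertoire(["CARDYW", "CAAAFW", "CARDYW", "CAAAFW"])
        assert uniformity(rep, ["s0"], CDR3_ONLY) == 0.0
        # duplicated clonotypes: avg density 0 -> uniformity 0 by convention
        assert uniformity(rep, ["s0", "s2"], CDR3_ONLY) == 0.0
        # two-member cluster: both local densities equal -> 0
        assert uniformity(rep, ["s0", "s1"], CDR3_ONLY) == 0.0

    def test_uniformity_absolute_deviation_form(self):
        rep = make_repertoire(["AAAAAAAAAA", "AAAAAAAAAC", "AAACCCAAAC"])
        # locals: 0.1, 0.1, 0.3; avg 1/6... recompute: s1-s2 differ at 3,4,5 -> 0.7
        members = ["s0", "s1", "s2"]
        locals_ = [local_density(rep, m, members, CDR3_ONLY) for m in members]
        assert locals_ == pytest.approx([0.1, 0.1, 0.3])
        avg = np.mean(locals_)
        expected = sum(abs(x - avg) for x in locals_) / avg
        assert uniformity(rep, members, CDR3_ONLY) == pytest.approx(expected)
        # the literal signed form cancels to zero by construction
        assert uniformity(rep, members, CDR3_ONLY, literal=True) == pytest.approx(0.0)


class TestMergeSingletons:
    def chain_cluster(self, n, spacing):
        """Crafted cluster 0..n-1 where every local density is `spacing`."""
        return {(i, i + 1): spacing for i in range(n - 1)}

    def test_singleton_at_cluster_spacing_is_absorbed(self):
        n = 5
        entries = self.chain_cluster(4, 0.1)
        # far pairs inside the cluster
        for i in range(4):
            for j in range(i + 2, 4):
                entries[(i, j)] = 0.5
        entries.update({(4, 3): 0.1, (4, 0): 0.6, (4, 1): 0.6, (4, 2): 0.6})
        rep = dummy_rep(n)
        dist = crafted(n, entries)
        cl = Clustering.from_clusters({"k": ["s0", "s1", "s2", "s3"], "z": ["s4"]})
        out = merge_singletons(rep, cl, rcfg=RefineConfig(delta=0.05), dist=dist)
        assert out.n_clusters == 1

    def test_remote_singleton_not_absorbed(self):
        n = 5
        entries = self.chain_cluster(4, 0.1)
        for i in range(4):
            entries[(4, i)] = 1.0  # 10x the cluster's average density
        rep = dummy_rep(n)
        dist = crafted(n, entries)
        cl = Clustering.from_clusters({"k": ["s0", "s1", "s2", "s3"], "z": ["s4"]})
        out = merge_singletons(rep, cl, rcfg=RefineConfig(delta=0.05), dist=dist)
        assert out.same_partition(cl)

    def test_delta_zero_never_merges(self):
        rep = make_repertoire(["CARDYW", "CARDFW", "CAAAAW"])
        cl = Clustering.from_clusters({"a": ["s0", "s1"], "z": ["s2"]})
        out = merge_singletons(rep, cl, CDR3_ONLY, RefineConfig(delta=0.0))
        assert out.same_partition(cl)

    def test_all_singletons_pair_up(self):
        # nearest-neighbour singletons merge (uniformity change is zero)
        rep = make_repertoire(["AAAAA", "AAAAC", "CARDW"])
        cl = Clustering.from_clusters({"a": ["s0"], "b": ["s1"], "c": ["s2"]})
        out = merge_singletons(rep, cl, CDR3_ONLY, RefineConfig(delta=0.05))
        assert out.n_clusters < 3


class TestInvariantProperties:
    def test_merging_never_increases_cluster_count_and_reaches_fixed_point(self):
        rng = np.random.default_rng(21)
        for trial in range(10):
            n = int(rng.integers(8, 40))
            rep = dummy_rep(n)
            dist = rng.uniform(0, 1, size=(n, n))
            dist = (dist + dist.T) / 2
            np.fill_diagonal(dist, 0.0)
            labels = rng.integers(0, max(2, n // 4), size=n)
            cl = Clustering({f"s{i}": f"c{labels[i]:02d}" for i in range(n)})
            refined = refine(rep, cl, dist=dist)
            assert refined.n_clusters <= cl.n_clusters
            final = merge_singletons(rep, refined, dist=dist)
            assert final.n_clusters <= refined.n_clusters
            # fixed point: no sequence of a multi-member cluster has a_i > b_i
            pos = {f"s{i}": i for i in range(n)}
            clusters = {l: [pos[m] for m in ms] for l, ms in refined.clusters.items()}
            if len(clusters) >= 2:
                for label, members in clusters.items():
                    if len(members) < 2:
                        continue
                    for i in members:
                        a_i = np.mean([dist[i, j] for j in members if j != i])
                        b_i = min(
                            np.mean([dist[i, j] for j in other])
                            for lab, other in clusters.items()
                            if lab != label
                        )
                        assert a_i <= b_i + 1e-12
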