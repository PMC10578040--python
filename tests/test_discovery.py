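"""k-means discovery, k selection, partition agreement, profile matching and
cross-dataset consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lupus_endotypes.discovery import (ClusteringResult, adjusted_rand_index,
                                       choose_k, consensus_merge, cosine_match,
                                       cosine_similarity_matrix, kmeans,
                                       relabel_to_reference, relabel_samples)


def _blobs(centers, n_per, sd, seed=0, feature_names=None):
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    X, y = [], []
    for c, center in enumerate(centers):
        X.append(center + rng.normal(0, sd, size=(n_per, len(center))))
        y += [c] * n_per
    X = np.vstack(X)
    cols = [f"s{i}" for i in range(len(X))]
    rows = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X.T, index=rows, columns=cols), np.array(y)


class TestKmeans:
    def test_separated_blobs_recovered_exactly(self):
        df, truth = _blobs([[0, 0, 0], [10, 10, 10]], 25, sd=1.0)
        res = kmeans(df, 2, n_restarts=20, seed=0)
        assert adjusted_rand_index(res.labels, truth) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        df, _ = _blobs([[0, 0], [5, 5]], 3, sd=0.5, seed=1)
        res = kmeans(df, df.shape[1], n_restarts=5, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-9)

    def test_inertia_matches_recomputation(self):
        df, _ = _blobs([[0, 0], [4, 4]], 10, sd=1.0, seed=2)
        res = kmeans(df, 3, n_restarts=20, seed=0)
        X = df.to_numpy().T
        C = res.centroids.to_numpy()
        d2 = ((X[:, None, :] - C[None]) ** 2).sum(axis=2).min(axis=1).sum()
        assert res.inertia == pytest.approx(d2, rel=1e-9)

    def test_matches_exhaustive_partition_oracle(self):
        # all 2-cluster partitions of 8 points: the best achievable inertia
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        df = pd.DataFrame(X.T, index=["f0", "f1"],
                          columns=[f"s{i}" for i in range(8)])
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=8):
            a = np.array(assignment)
            if a.min() == a.max():
                continue
            inertia = 0.0
            for c in (0, 1):
                pts = X[a == c]
                inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
            best = min(best, inertia)
        res = kmeans(df, 2, n_restarts=100, seed=0)
        assert res.inertia == pytest.approx(best, rel=1e-9)

    def test_k_larger_than_n_rejected(self):
        df, _ = _blobs([[0, 0]], 3, sd=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(df, 5, n_restarts=2, seed=0)

    def test_inertia_non_increasing_in_k(self):
        df, _ = _blobs([[0, 0, 0], [4, 0, 0], [0, 4, 0]], 15, sd=1.0, seed=5)
        inertias = [kmeans(df, k, n_restarts=50, seed=0).inertia
                    for k in range(2, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


class TestChooseK:
    def test_planted_four_clusters_found_by_both_rules(self):
        centers = np.eye(4) * 8
        df, _ = _blobs(centers, 30, sd=0.8, seed=6)
        report = choose_k(df, range(2, 9), n_restarts=20, seed=0)
        assert report["k_silhouette"] == 4
        assert report["k_elbow"] == 4
        assert report["k_selected"] == 4
        assert report["inertia_monotone"]

    def test_single_blob_has_weak_silhouette_everywhere(self):
        df, _ = _blobs([[0, 0, 0, 0]], 80, sd=1.0, seed=7)
        report = choose_k(df, range(2, 7), n_restarts=20, seed=0)
        assert max(report["silhouette"]) < 0.3

    def test_duplicate_point_clusters_reach_silhouette_one(self):
        X = np.array([[0.0, 0.0]] * 5 + [[9.0, 9.0]] * 5)
        df = pd.DataFrame(X.T, index=["f0", "f1"],
                          columns=[f"s{i}" for i in range(10)])
        report = choose_k(df, [2], n_restarts=5, seed=0)
        assert report["silhouette"][0] == pytest.approx(1.0)

    def test_bad_k_range_rejected(self):
        df, _ = _blobs([[0, 0]], 5, sd=1.0)
        with pytest.raises(ValueError, match="k_range"):
            choose_k(df, range(1, 3), seed=0)


class TestAdjustedRandIndex:
    def test_identical_labelings_score_one(self):
        assert adjusted_rand_index([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == 1.0

    def test_single_cluster_vs_anything_scores_zero(self):
        assert adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 0]) == pytest.approx(0.0)

    def test_hand_contingency_cases(self):
        # diagonal table [[2,0],[0,2]]: perfect agreement
        assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
        # uniform table [[1,1],[1,1]]: index sum_ij C(n_ij,2) = 0,
        # expected = 2*2/C(4,2) = 2/3, max = (2+2)/2 = 2 -> ARI = -0.5
        expected = (0 - 2 / 3) / (2 - 2 / 3)
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(expected)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 4, 40)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        relabeled = np.array([{0: 2, 1: 0, 2: 1}[x] for x in a])
        assert adjusted_rand_index(relabeled, b) == pytest.approx(
            adjusted_rand_index(a, b))


class TestCosineMatch:
    def test_identical_profiles_match_at_one(self):
        prof = pd.DataFrame([[1.0, 0.2, -0.3], [0.1, 0.8, 0.5]],
                            index=["x", "y"], columns=list("abc"))
        res = cosine_match(prof, prof.rename(index={"x": "u", "y": "v"}))
        assert {(a, b) for a, b, _ in res["pairs"]} == {("x", "u"), ("y", "v")}
        assert all(s == pytest.approx(1.0) for _, _, s in res["pairs"])

    def test_orthogonal_profiles_stay_unique(self):
        a = pd.DataFrame([[1.0, 0.0]], index=["x"], columns=["f0", "f1"])
        b = pd.DataFrame([[0.0, 1.0]], index=["y"], columns=["f0", "f1"])
        res = cosine_match(a, b, threshold=0.7)
        assert res["pairs"] == []
        assert res["unique_a"] == ["x"] and res["unique_b"] == ["y"]

    def test_negated_profile_has_similarity_minus_one(self):
        a = pd.DataFrame([[0.5, -0.4, 0.8]], index=["x"], columns=list("abc"))
        sim = cosine_similarity_matrix(a, -a.rename(index={"x": "y"}))
        assert sim.loc["x", "y"] == pytest.approx(-1.0)


class TestConsensusMerge:
    @staticmethod
    def _planted_profiles(n_datasets=5, noise=0.05, seed=9):
        """8 planted endotype profiles observed with small noise in several
        pseudo-datasets; distinct profiles are far apart (>> cut height)."""
        rng = np.random.default_rng(seed)
        base = np.zeros((8, 32))
        for e in range(8):
            base[e, : 4 * e] = 0.95  # adjacent profiles 1.9 apart (> cut 1.8)
        rows, names = [], []
        for d in range(n_datasets):
            present = rng.choice(8, size=rng.integers(4, 9), replace=False)
            for e in present:
                rows.append(base[e] + rng.normal(0, noise, 32))
                names.append(f"d{d}:e{e}")
        return pd.DataFrame(rows, index=names,
                            columns=[f"f{i}" for i in range(32)]), base

    def test_duplicated_profiles_merge_back_to_originals(self):
        prof, _ = self._planted_profiles(n_datasets=1, noise=0.0)
        doubled = pd.concat([prof, prof.rename(index=lambda s: s + "_copy")])
        model = consensus_merge(doubled, cut_height=0.5)
        assert len(model.endotype_ids) == prof.shape[0]

    def test_recovers_eight_planted_endotypes_at_default_cut(self):
        prof, base = self._planted_profiles()
        model = consensus_merge(prof, cut_height=1.8)
        assert len(model.endotype_ids) == 8
        # every member group is pure: one planted endotype per final group
        for members in model.members.values():
            assert len({m.split(":")[1] for m in members}) == 1

    def test_zero_cut_keeps_every_profile(self):
        prof, _ = self._planted_profiles(n_datasets=2, seed=10)
        model = consensus_merge(prof, cut_height=0.0)
        assert len(model.endotype_ids) == prof.shape[0]

    def test_group_count_non_increasing_in_cut_height(self):
        prof, _ = self._planted_profiles(seed=11)
        counts = [len(consensus_merge(prof, cut_height=h).endotype_ids)
                  for h in (0.0, 0.5, 1.8, 4.0, 50.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1


class TestRelabelToReference:
    def test_reference_centroids_map_to_themselves(self):
        prof, base = TestConsensusMerge._planted_profiles(n_datasets=3, seed=12)
        model = consensus_merge(prof, cut_height=1.8)
        local = ClusteringResult(labels=pd.Series(dtype=int),
                                 centroids=model.profiles.copy(),
                                 inertia=0.0, k=8, n_restarts=1, seed=0)
        res = relabel_to_reference(local, model)
        assert res["mapping"] == {e: e for e in model.endotype_ids}
        assert res["below_threshold"] == []

    def test_mapping_invariant_to_local_cluster_numbering(self):
        prof, _ = TestConsensusMerge._planted_profiles(n_datasets=3, seed=13)
        model = consensus_merge(prof, cut_height=1.8)
        cents = model.profiles.copy()
        cents.index = range(len(cents))
        shuffled = cents.iloc[::-1]
        a = relabel_to_reference(
            ClusteringResult(pd.Series(dtype=int), cents, 0.0, 8, 1, 0), model)
        b = relabel_to_reference(
            ClusteringResult(pd.Series(dtype=int), shuffled, 0.0, 8, 1, 0), model)
        for c in cents.index:
            assert a["mapping"][c] == b["mapping"][c]

    def test_samples_relabel_to_their_planted_endotype(self):
        prof, base = TestConsensusMerge._planted_profiles(n_datasets=4, seed=14)
        model = consensus_merge(prof, cut_height=1.8)
        rng = np.random.default_rng(15)
        truth, rows, ids = [], [], []
        for i in range(60):
            e = int(rng.integers(0, 8))
            rows.append(base[e] + rng.normal(0, 0.05, 32))
            truth.append(e)
            ids.append(f"s{i}")
        samples = pd.DataFrame(np.array(rows).T,
                               index=[f"f{i}" for i in range(32)], columns=ids)
        assigned = relabel_samples(samples, model, metric="euclidean")
        # the mapping planted endotype -> letter must be one-to-one
        table = pd.crosstab(pd.Series(truth, index=ids), assigned)
        assert (table.gt(0).sum(axis=1) == 1).all()
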