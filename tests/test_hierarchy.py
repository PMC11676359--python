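"""Hierarchy-alignment statistics: centroids, distance matrices, MAD,
Spearman, Welch t-test, dendrogram."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lorentznet.hierarchy import (BootstrapConfig, DistanceMatrix, EmbeddingSet,
                                  class_centroids, compare_models_ttest, dendrogram,
                                  ground_truth_matrix, mean_absolute_difference,
                                  model_distance_matrix, normalize_matrix,
                                  spearman_alignment)
from lorentznet.lorentz import LorentzManifold, expmap0, geodesic_distance


def toy_descriptors(n=6):
    # 2 modalities x 3 diseases
    rows = []
    for i in range(n):
        rows.append({"class_id": i, "modality": f"m{i // 3}", "disease": f"d{i % 3}"})
    return pd.DataFrame(rows)


class TestClassCentroids:
    def test_single_sample_centroid_is_the_sample(self):
        emb = EmbeddingSet(np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([0, 1]))
        np.testing.assert_array_equal(class_centroids(emb), emb.matrix)

    def test_symmetric_pair_averages_to_zero(self):
        emb = EmbeddingSet(np.array([[1.0, -2.0], [-1.0, 2.0]]), np.array([0, 0]))
        np.testing.assert_allclose(class_centroids(emb), [[0.0, 0.0]])

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 4, 40)
        y[:4] = np.arange(4)  # every class present
        emb = EmbeddingSet(X, y)
        oracle = pd.DataFrame(X).groupby(y).mean().to_numpy()
        np.testing.assert_allclose(class_centroids(emb), oracle, atol=1e-12)

    def test_missing_class_raises_with_ids(self):
        emb = EmbeddingSet(np.zeros((2, 2)), np.array([0, 3]))
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            class_centroids(emb)


class TestFrechetCentroids:
    def test_agrees_with_tangent_mean_for_tight_clusters(self):
        from lorentznet.hierarchy import frechet_centroids

        m = LorentzManifold(k=1.0)
        rng = np.random.default_rng(13)
        base = rng.normal(size=(3, 4)) * 0.3
        rows = np.repeat(base, 10, axis=0) + rng.normal(scale=0.01, size=(30, 4))
        emb = EmbeddingSet(rows, np.repeat(np.arange(3), 10), geometry="lorentz")
        tangent = class_centroids(emb)
        frechet = frechet_centroids(emb, m)
        # for tightly clustered points the Karcher mean and tangent mean agree
        np.testing.assert_allclose(frechet, tangent, atol=1e-3)


class TestModelDistanceMatrix:
    def test_identical_centroids_give_zero_matrix(self):
        D = model_distance_matrix(np.ones((3, 2)), "euclidean")
        np.testing.assert_array_equal(D.values, np.zeros((3, 3)))

    def test_collinear_euclidean_distances(self):
        c = np.array([[0.0], [1.0], [3.0]])
        D = model_distance_matrix(c, "euclidean")
        np.testing.assert_allclose(D.values,
                                   [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_lorentz_matrix_matches_pairwise_scalar_oracle(self):
        m = LorentzManifold(k=1.5)
        rng = np.random.default_rng(1)
        cents = rng.normal(size=(5, 3)) * 0.5
        D = model_distance_matrix(cents, "lorentz", m)
        pts = expmap0(cents, m)
        for i in range(5):
            for j in range(5):
                assert abs(D.values[i, j]
                           - geodesic_distance(pts[i], pts[j], m)) < 1e-9

    def test_geometry_manifold_mismatch(self):
        with pytest.raises(ValueError):
            model_distance_matrix(np.zeros((2, 2)), "lorentz", None)
        with pytest.raises(ValueError):
            model_distance_matrix(np.zeros((2, 2)), "euclidean", LorentzManifold())


class TestGroundTruthMatrix:
    def test_identical_rows_rejected_and_zero_distance_for_self(self):
        df = toy_descriptors()
        D = ground_truth_matrix(df, level_weights=[2.0, 1.0])
        assert np.all(np.diag(D.values) == 0)
        dup = pd.concat([df, df.iloc[[0]].assign(class_id=99)])
        with pytest.raises(ValueError, match="duplicate"):
            ground_truth_matrix(dup, level_weights=[2.0, 1.0])

    def test_single_level_mismatch_costs_that_weight(self):
        df = pd.DataFrame([
            {"class_id": 0, "a": "x", "b": "y", "c": "z", "d": "w"},
            {"class_id": 1, "a": "x", "b": "y", "c": "z", "d": "q"},
        ])
        D = ground_truth_matrix(df, level_weights=[4, 3, 2, 1])
        assert D.values[0, 1] == 1.0

    def test_full_matrix_matches_hand_enumeration(self):
        D = ground_truth_matrix(toy_descriptors(), level_weights=[2.0, 1.0])
        # classes: (m0,d0),(m0,d1),(m0,d2),(m1,d0),(m1,d1),(m1,d2)
        expected = np.array([
            [0, 1, 1, 2, 3, 3],
            [1, 0, 1, 3, 2, 3],
            [1, 1, 0, 3, 3, 2],
            [2, 3, 3, 0, 1, 1],
            [3, 2, 3, 1, 0, 1],
            [3, 3, 2, 1, 1, 0],
        ], dtype=float)
        np.testing.assert_array_equal(D.values, expected)

    def test_default_weights_descend_coarse_to_fine(self):
        df = toy_descriptors()
        D = ground_truth_matrix(df)  # weights (2, 1)
        ref = ground_truth_matrix(df, level_weights=[2, 1])
        np.testing.assert_array_equal(D.values, ref.values)


class TestNormalizeMatrix:
    def test_scales_max_off_diagonal_to_one(self):
        D = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0]], float))
        N = normalize_matrix(D)
        np.testing.assert_allclose(
            N.values, [[0, 0.5, 1], [0.5, 0, 0.5], [1, 0.5, 0]])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(4, 3))
        D = normalize_matrix(model_distance_matrix(c, "euclidean"))
        again = normalize_matrix(D)
        np.testing.assert_allclose(again.values, D.values, atol=1e-15)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_matrix(DistanceMatrix(np.zeros((3, 3))))


class TestMeanAbsoluteDifference:
    def _norm(self, values):
        return normalize_matrix(DistanceMatrix(np.asarray(values, float)))

    def test_identical_matrices_give_zero(self):
        D = self._norm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        mad, ci = mean_absolute_difference(D, D, BootstrapConfig(seed=0))
        assert mad == 0.0
        assert ci == (0.0, 0.0)

    def test_three_class_hand_enumeration(self):
        Dm = self._norm([[0, 1, 2], [1, 0, 2], [2, 2, 0]])
        Dg = self._norm([[0, 2, 2], [2, 0, 1], [2, 1, 0]])
        mad, ci = mean_absolute_difference(Dm, Dg, BootstrapConfig(seed=1))
        # pairs (0,1): |0.5-1|, (0,2): |1-1|, (1,2): |1-0.5| -> mean = 1/3
        assert abs(mad - 1.0 / 3.0) < 1e-12
        assert ci[0] <= mad <= ci[1]

    def test_unnormalized_input_rejected(self):
        D = DistanceMatrix(np.array([[0, 2.0], [2.0, 0]]))
        with pytest.raises(ValueError, match="normalis"):
            mean_absolute_difference(D, D)

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(3)
        Dm = normalize_matrix(model_distance_matrix(rng.normal(size=(6, 3)), "euclidean"))
        Dg = normalize_matrix(ground_truth_matrix(toy_descriptors()))
        a = mean_absolute_difference(Dm, Dg, BootstrapConfig(seed=9))
        b = mean_absolute_difference(Dm, Dg, BootstrapConfig(seed=9))
        assert a == b


class TestSpearman:
    def _pair(self):
        rng = np.random.default_rng(4)
        Dg = normalize_matrix(ground_truth_matrix(toy_descriptors()))
        Dm = normalize_matrix(model_distance_matrix(rng.normal(size=(6, 3)), "euclidean"))
        return Dm, Dg

    def test_self_correlation_is_one(self):
        _, Dg = self._pair()
        rho, _ = spearman_alignment(Dg, Dg)
        assert abs(rho - 1.0) < 1e-12

    def test_reversed_distinct_ranks_give_minus_one(self):
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        Dm = normalize_matrix(DistanceMatrix(vals))
        rev = normalize_matrix(DistanceMatrix(vals.max() - vals + np.diag([vals.max()] * 3) * 0
                                              - np.diag(np.full(3, vals.max() - 0))))
        # build explicitly: max - entry, diagonal forced back to zero
        rv = vals.max() - vals
        np.fill_diagonal(rv, 0.0)
        rev = normalize_matrix(DistanceMatrix(rv))
        rho, _ = spearman_alignment(Dm, rev)
        assert abs(rho + 1.0) < 1e-12

    def test_matches_rank_formula_oracle_on_distinct_entries(self):
        rng = np.random.default_rng(5)
        Dm, Dg = self._pair()
        a, b = Dm.upper_triangle(), Dg.upper_triangle()
        rho, _ = spearman_alignment(Dm, Dg)
        # tie-corrected oracle: Pearson correlation of the rank vectors
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert abs(rho - oracle) < 1e-12

    def test_permutation_of_class_order_is_invariant(self):
        rng = np.random.default_rng(6)
        cents = rng.normal(size=(6, 4))
        df = toy_descriptors()
        perm = rng.permutation(6)
        D1 = normalize_matrix(model_distance_matrix(cents, "euclidean"))
        G1 = normalize_matrix(ground_truth_matrix(df))
        D2 = normalize_matrix(model_distance_matrix(cents[perm], "euclidean"))
        G2 = normalize_matrix(ground_truth_matrix(
            df.iloc[perm].assign(class_id=range(6)).reset_index(drop=True)))
        rho1, _ = spearman_alignment(D1, G1)
        rho2, _ = spearman_alignment(D2, G2)
        assert abs(rho1 - rho2) < 1e-12

    def test_constant_vector_rejected(self):
        ones = np.ones((3, 3)) - np.eye(3)
        D = DistanceMatrix(ones)
        with pytest.raises(ValueError, match="constant"):
            spearman_alignment(D, D)


class TestWelchTTest:
    def test_identical_vectors_give_t0_p1(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        t, p = compare_models_ttest(v, v)
        assert t == 0.0 and abs(p - 1.0) < 1e-12

    def test_well_separated_vectors_give_tiny_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.1, 0.01, 50)
        b = rng.normal(0.3, 0.01, 50)
        t, p = compare_models_ttest(a, b)
        assert p < 1e-4
        assert t < 0

    def test_swapping_arguments_flips_t_sign(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=30), rng.normal(1.0, 1.0, 30)
        t1, p1 = compare_models_ttest(a, b)
        t2, p2 = compare_models_ttest(b, a)
        assert abs(t1 + t2) < 1e-12 and abs(p1 - p2) < 1e-12

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=20), rng.normal(0.5, 2.0, 25)
        t, p = compare_models_ttest(a, b)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=False)
        assert (t, p) == (float(ref_t), float(ref_p))

    def test_double_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_models_ttest(np.ones(5), np.ones(5))


class TestDendrogram:
    def test_n_minus_one_merges(self):
        rng = np.random.default_rng(10)
        Z = dendrogram(rng.normal(size=(7, 3)), "euclidean")
        assert Z.shape == (6, 4)

    def test_tight_pair_merges_first(self):
        cents = np.array([[0.0, 0], [0.1, 0], [5.0, 5.0]])
        Z = dendrogram(cents, "euclidean")
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_average_linkage_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        Z = dendrogram(rng.normal(size=(10, 4)), "euclidean")
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_lorentz_geometry_supported(self):
        m = LorentzManifold(k=1.0)
        rng = np.random.default_rng(12)
        Z = dendrogram(rng.normal(size=(5, 3)) * 0.3, "lorentz", m)
        assert Z.shape == (4, 4)
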