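"""Missingness filters, standardization, heat-kernel similarity, KNN graphs."""

import numpy as np
import pytest

from smmsn.preprocess import (OmicsView, PreprocessConfig, build_knn_graph,
                              filter_missing, heat_kernel_similarity,
                              normalize_adjacency, normalize_features,
                              preprocess_views)
from conftest import make_view


def view_with_nans(shape, nan_at, rng=None):
    rng = rng or np.random.default_rng(0)
    X = rng.standard_normal(shape)
    for i, j in nan_at:
        X[i, j] = np.nan
    return make_view(X)


class TestFilterMissing:
    def test_sample_over_threshold_dropped(self):
        # one sample missing 3/10 = 30% > 20% -> dropped; others kept
        v = view_with_nans((10, 10), [(4, 0), (4, 1), (4, 2)])
        out, rep = filter_missing(v)
        assert rep["dropped_samples"] == ["S4"]
        assert out.n_samples == 9 and out.n_features == 10
        assert not np.isnan(out.X).any()

    def test_clean_view_unchanged(self, small_view):
        out, rep = filter_missing(small_view)
        np.testing.assert_array_equal(out.X, small_view.X)
        assert rep["dropped_samples"] == [] and rep["dropped_features"] == []

    def test_feature_filter_matches_brute_force(self):
        # 5x5: feature f1 missing in 2/5 samples (40%); each affected sample
        # is missing exactly 1/5 = 20%, not strictly above the threshold
        v = view_with_nans((5, 5), [(0, 1), (3, 1)])
        out, rep = filter_missing(v)
        # independent exhaustive scan of every row/column fraction
        miss = np.isnan(v.X)
        assert all(miss[i].mean() <= 0.2 for i in range(5))
        bad_cols = [j for j in range(5) if miss[:, j].mean() > 0.2]
        assert rep["dropped_features"] == [f"f{j}" for j in bad_cols] == ["f1"]
        assert out.n_features == 4 and out.n_samples == 5

    def test_samples_filtered_before_features(self):
        # sample S0 missing 50%; after dropping it, f0 is complete and kept
        v = view_with_nans((4, 4), [(0, 0), (0, 1)])
        out, rep = filter_missing(v)
        assert rep["dropped_samples"] == ["S0"]
        assert rep["dropped_features"] == []

    def test_residual_gaps_mean_imputed(self):
        v = view_with_nans((10, 5), [(2, 3)])
        out, _ = filter_missing(v)
        observed = np.delete(v.X[:, 3], 2)
        assert out.X[2, 3] == pytest.approx(observed.mean())

    def test_idempotent(self):
        v = view_with_nans((10, 10), [(4, 0), (4, 1), (4, 2), (0, 5)])
        once, _ = filter_missing(v)
        twice, rep = filter_missing(once)
        np.testing.assert_array_equal(once.X, twice.X)
        assert rep["dropped_samples"] == [] and rep["dropped_features"] == []

    def test_all_samples_dropped_is_error(self):
        X = np.full((3, 4), np.nan)
        with pytest.raises(ValueError, match="v"):
            filter_missing(make_view(X))


class TestNormalizeFeatures:
    def test_hand_computed_column(self):
        out = normalize_features(make_view(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(
            out.X.ravel(), [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.standard_normal((50, 5))
        once = normalize_features(make_view(X))
        twice = normalize_features(once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalize_features(make_view(X))
        assert out.features == ["f0", "f2"]

    def test_columns_centered_and_unit_spread(self, rng):
        X = rng.standard_normal((40, 7)) * 3 + 2
        out = normalize_features(make_view(X))
        assert np.abs(out.X.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(out.X.std(axis=0), 1.0, atol=1e-9)


class TestHeatKernel:
    def test_identical_rows_have_unit_similarity(self):
        v = make_view(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
        S = heat_kernel_similarity(v, PreprocessConfig(sigma_mode="fixed", sigma_value=2.0))
        assert S[0, 1] == pytest.approx(1.0)

    def test_distance_equal_sigma_gives_inverse_e(self):
        v = make_view(np.array([[0.0], [2.0]]))  # squared distance 4
        S = heat_kernel_similarity(v, PreprocessConfig(sigma_mode="fixed", sigma_value=4.0))
        assert S[0, 1] == pytest.approx(np.exp(-1.0))

    def test_large_sigma_limit(self, rng):
        v = make_view(rng.standard_normal((6, 3)))
        S = heat_kernel_similarity(v, PreprocessConfig(sigma_mode="fixed", sigma_value=1e12))
        np.testing.assert_allclose(S, 1.0, atol=1e-9)

    def test_entries_in_unit_interval_and_monotone(self, rng):
        v = make_view(rng.standard_normal((20, 4)))
        S = heat_kernel_similarity(v, PreprocessConfig())
        assert (S > 0).all() and (S <= 1.0).all()
        np.testing.assert_allclose(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)
        # monotone decreasing in squared distance
        from scipy.spatial.distance import squareform, pdist
        d2 = squareform(pdist(v.X, "sqeuclidean"))
        iu = np.triu_indices(20, 1)
        order = np.argsort(d2[iu])
        assert (np.diff(S[iu][order]) <= 1e-12).all()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sigma_mode="fixed", sigma_value=0.0)


class TestKnnGraph:
    def test_line_graph_matches_brute_force(self):
        # points 0, 1, 3 on a line, K=1: nearest of 0 is 1, of 1 is 0, of 3 is 1
        v = make_view(np.array([[0.0], [1.0], [3.0]]))
        S = heat_kernel_similarity(v, PreprocessConfig(sigma_mode="fixed", sigma_value=1.0))
        g = build_knn_graph(S, PreprocessConfig(k_neighbors=1))
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(g.A, expected)

    def test_k_saturates_to_complete_graph(self, rng):
        v = make_view(rng.standard_normal((6, 2)))
        S = heat_kernel_similarity(v, PreprocessConfig())
        g = build_knn_graph(S, PreprocessConfig(k_neighbors=5))
        np.testing.assert_array_equal(g.A, 1.0 - np.eye(6))

    def test_k_clamped_with_warning_when_too_large(self, rng, caplog):
        v = make_view(rng.standard_normal((5, 2)))
        S = heat_kernel_similarity(v, PreprocessConfig())
        g = build_knn_graph(S, PreprocessConfig(k_neighbors=40))
        np.testing.assert_array_equal(g.A, 1.0 - np.eye(5))

    def test_adjacency_symmetric_zero_diagonal(self, rng):
        v = make_view(rng.standard_normal((30, 3)))
        S = heat_kernel_similarity(v, PreprocessConfig())
        g = build_knn_graph(S, PreprocessConfig(k_neighbors=4))
        np.testing.assert_array_equal(g.A, g.A.T)
        np.testing.assert_array_equal(np.diag(g.A), 0.0)
        np.testing.assert_allclose(g.A_norm, g.A_norm.T)
        # every row selected at least K neighbours before symmetrization
        assert (g.A.sum(axis=1) >= 4).all()

    def test_separated_blobs_have_no_cross_edges(self, rng):
        # 3 blobs of 10 points, far apart; K=5 < blob size
        centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        X = np.vstack([c + 0.5 * rng.standard_normal((10, 2)) for c in centers])
        v = make_view(X)
        S = heat_kernel_similarity(v, PreprocessConfig())
        g = build_knn_graph(S, PreprocessConfig(k_neighbors=5))
        blob = np.repeat(np.arange(3), 10)
        cross = g.A[blob[:, None] != blob[None, :]]
        assert cross.sum() == 0

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            build_knn_graph(np.array([[1.0]]), PreprocessConfig(k_neighbors=1))


class TestNormalizeAdjacency:
    def test_isolated_node(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_two_connected_nodes(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_symmetric_nonnegative(self, rng):
        A = (rng.random((8, 8)) > 0.6).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0.0)
        An = normalize_adjacency(A)
        np.testing.assert_allclose(An, An.T)
        assert (An >= 0).all()


def test_pipeline_aligns_views_and_reports(rng):
    X1 = rng.standard_normal((12, 6))
    X1[0, :3] = np.nan  # S0 dropped from view 1 (50% missing)
    v1 = make_view(X1, "a")
    v2 = make_view(rng.standard_normal((12, 4)), "b")
    views, graphs, report = preprocess_views([v1, v2], PreprocessConfig(k_neighbors=3))
    assert views[0].samples == views[1].samples
    assert "S0" not in views[0].samples
    assert len(graphs) == 2
    assert report["views"][0]["dropped_samples"] == ["S0"]
    assert report["views"][0]["sigma"] > 0
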