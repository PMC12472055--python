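import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutromet import (
    InvariantError,
    fit_pca,
    fit_plsda,
    predict_plsda,
    project,
    vip_scores,
)


def two_class_data(rng, n_per_class=8, p=5, sep=3.0):
    Xa = rng.normal(size=(n_per_class, p))
    Xb = rng.normal(size=(n_per_class, p))
    Xb[:, 0] += sep
    X = np.vstack([Xa, Xb])
    y = ["A"] * n_per_class + ["B"] * n_per_class
    return X, y


class TestPCA:
    def test_collinear_points_have_unit_first_ratio(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t, -t, 0.5 * t])
        model = fit_pca(X, 2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(0)
        model = fit_pca(rng.normal(size=(8, 5)), 4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        """Brute-force eigensolver of the covariance matrix as oracle."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 4))
        model = fit_pca(X, 3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        ratio = evals / evals.sum()
        np.testing.assert_allclose(
            model.explained_variance_ratio, ratio[:3], atol=1e-6
        )
        for k in range(3):
            dot = abs(model.loadings[:, k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-6)
        # scores match up to the sign convention
        ref = Xc @ evecs[:, :3]
        for k in range(3):
            sign = np.sign(model.scores[:, k] @ ref[:, k])
            np.testing.assert_allclose(model.scores[:, k], sign * ref[:, k], atol=1e-6)

    def test_explained_variance_permutation_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 4))
        a = fit_pca(X, 3).explained_variance_ratio
        b = fit_pca(X[rng.permutation(9)], 3).explained_variance_ratio
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_k_too_large_raises(self):
        with pytest.raises(InvariantError):
            fit_pca(np.zeros((3, 5)), 4)


class TestPLSDA:
    def test_informative_column_dominates_first_weight(self):
        rng = np.random.default_rng(1)
        n = 10
        X = rng.normal(scale=0.5, size=(2 * n, 6))
        X[:, 2] = np.r_[np.ones(n), -np.ones(n)] + rng.normal(scale=0.05, size=2 * n)
        y = ["A"] * n + ["B"] * n
        model = fit_plsda(X, y, 2)
        w1 = np.abs(model.weights[:, 0])
        assert np.argmax(w1) == 2

    def test_score_columns_orthogonal(self):
        rng = np.random.default_rng(2)
        X, y = two_class_data(rng, 10, 8, sep=1.5)
        model = fit_plsda(X, y, 4)
        T = model.scores
        for a in range(4):
            for b in range(a + 1, 4):
                assert abs(T[:, a] @ T[:, b]) < 1e-6 * np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b]) + 1e-6

    def test_first_weight_matches_svd_oracle(self):
        """Component-1 weight equals the dominant left singular vector of
        X_c' Y_c (the PLS covariance criterion)."""
        rng = np.random.default_rng(11)
        X, y = two_class_data(rng, 5, 4, sep=2.0)
        model = fit_plsda(X, y, 2)
        Xc = X - X.mean(axis=0)
        Y = np.zeros((10, 2))
        for i, label in enumerate(y):
            Y[i, 0 if label == "A" else 1] = 1.0
        Yc = Y - Y.mean(axis=0)
        U, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        dom = U[:, 0]
        dot = abs(model.weights[:, 0] @ dom)
        assert dot == pytest.approx(1.0, abs=1e-6)

    def test_matches_sklearn_nipals_weights(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(4)
        X, y = two_class_data(rng, 7, 6, sep=1.0)
        Y = np.zeros((14, 2))
        for i, label in enumerate(y):
            Y[i, 0 if label == "A" else 1] = 1.0
        ref = sklearn.PLSRegression(n_components=2, scale=False).fit(X, Y)
        model = fit_plsda(X, y, 2)
        for k in range(2):
            dot = abs(model.weights[:, k] @ ref.x_weights_[:, k])
            assert dot == pytest.approx(1.0, abs=1e-5)

    def test_unit_norm_weights(self):
        rng = np.random.default_rng(5)
        X, y = two_class_data(rng)
        model = fit_plsda(X, y, 3)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-8
        )

    def test_small_class_raises(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(InvariantError, match="< 2"):
            fit_plsda(X, ["A", "A", "A", "A", "B"], 1)


class TestPrediction:
    def test_identity_covariance_reduces_to_nearest_centroid(self):
        rng = np.random.default_rng(6)
        X, y = two_class_data(rng, 8, 5, sep=1.0)
        model = fit_plsda(X, y, 2)
        model.score_covariance = np.eye(2)
        X_new = rng.normal(size=(20, 5))
        labels, dists = predict_plsda(model, X_new)
        T_new = project(model, X_new)
        for i in range(20):
            euclid = {
                c: np.linalg.norm(T_new[i] - model.class_score_means[c])
                for c in model.class_labels
            }
            assert labels[i] == min(euclid, key=euclid.get)
            for j, c in enumerate(model.class_labels):
                assert dists[i, j] == pytest.approx(euclid[c], rel=1e-9)

    def test_separable_training_data_all_predicted_correctly(self):
        rng = np.random.default_rng(7)
        X, y = two_class_data(rng, 10, 4, sep=8.0)
        model = fit_plsda(X, y, 2)
        labels, _ = predict_plsda(model, X)
        assert list(labels) == y

    def test_point_at_class_mean_has_zero_distance(self):
        rng = np.random.default_rng(8)
        X, y = two_class_data(rng, 6, 4, sep=3.0)
        model = fit_plsda(X, y, 2)
        # construct an X row whose projection lands on class A's score mean
        R = model.rotation
        t_target = model.class_score_means["A"]
        x = model.x_mean + (np.linalg.pinv(R.T) @ t_target)
        labels, dists = predict_plsda(model, x[None, :])
        j = model.class_labels.index("A")
        assert dists[0, j] == pytest.approx(0.0, abs=1e-8)
        assert labels[0] == "A"


class TestVIP:
    def test_sum_of_squares_equals_p(self):
        rng = np.random.default_rng(9)
        for n, p, k in [(12, 5, 2), (16, 8, 3), (10, 3, 1)]:
            X, y = two_class_data(rng, n // 2, p, sep=1.5)
            model = fit_plsda(X, y, k)
            vip = vip_scores(model)
            assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)

    def test_single_active_variable_gets_sqrt_p(self):
        """One-component model with weight (1,0,0,0) puts all importance on
        variable 1: VIP = (2, 0, 0, 0) for p = 4."""
        rng = np.random.default_rng(10)
        n = 12
        X = np.zeros((n, 4))
        X[:, 0] = np.r_[np.ones(6), -np.ones(6)]
        X[:, 1:] = rng.normal(scale=1e-8, size=(n, 3))
        y = ["A"] * 6 + ["B"] * 6
        model = fit_plsda(X, y, 1)
        vip = vip_scores(model)
        assert vip[0] == pytest.approx(2.0, abs=1e-4)
        np.testing.assert_allclose(vip[1:], 0.0, atol=1e-4)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_vip_identity_property(seed):
    rng = np.random.default_rng(seed)
    p = int(rng.integers(3, 9))
    k = int(rng.integers(1, 3))
    X, y = two_class_data(rng, 6, p, sep=float(rng.uniform(0.5, 4.0)))
    model = fit_plsda(X, y, k)
    vip = vip_scores(model)
    assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)
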