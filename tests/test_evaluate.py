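import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutromet import (
    InvariantError,
    bh_adjust,
    compute_metrics,
    fit_plsda,
    loocv_ber_curve,
    predict_plsda,
    replicated_evaluation,
    univariate_screen,
)


def clustered_data(rng, n_per_class=10, p=4, sep=10.0):
    X = rng.normal(size=(2 * n_per_class, p))
    X[n_per_class:, 0] += sep
    y = ["A"] * n_per_class + ["B"] * n_per_class
    return X, y


class TestMetrics:
    def test_hand_computed_confusion(self):
        # TP=3, TN=2, FP=1, FN=0 with positive class "P"
        y_true = ["P", "P", "P", "N", "N", "N"]
        y_pred = ["P", "P", "P", "P", "N", "N"]
        m = compute_metrics(y_true, y_pred, positive_class="P")
        assert m.accuracy == pytest.approx(0.8333, abs=1e-4)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.specificity == pytest.approx(0.6667, abs=1e-4)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.8571, abs=1e-4)
        assert m.balanced_accuracy == pytest.approx(0.8333, abs=1e-4)
        assert m.ber == pytest.approx(0.1667, abs=1e-4)

    def test_perfect_predictions(self):
        y = ["A", "B", "A", "B"]
        m = compute_metrics(y, y, positive_class="B")
        for name in ("accuracy", "balanced_accuracy", "sensitivity", "specificity",
                     "precision", "f1"):
            assert getattr(m, name) == 1.0
        assert m.ber == 0.0

    def test_complement_predictions(self):
        y_true = ["A", "B", "A", "B"]
        y_pred = ["B", "A", "B", "A"]
        m = compute_metrics(y_true, y_pred, positive_class="B")
        assert m.accuracy == 0.0
        assert m.ber == 1.0

    def test_binary_identities_hold(self):
        rng = np.random.default_rng(0)
        y_true = list(rng.choice(["A", "B"], size=40))
        y_pred = list(rng.choice(["A", "B"], size=40))
        m = compute_metrics(y_true, y_pred, positive_class="B")
        assert m.balanced_accuracy == pytest.approx(
            (m.sensitivity + m.specificity) / 2, abs=1e-12
        )
        assert m.ber == pytest.approx(1 - m.balanced_accuracy, abs=1e-12)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        y_true = list(rng.choice(["A", "B"], size=60))
        y_pred = list(rng.choice(["A", "B"], size=60))
        m = compute_metrics(y_true, y_pred, positive_class="B")
        assert m.accuracy == pytest.approx(sk.accuracy_score(y_true, y_pred))
        assert m.balanced_accuracy == pytest.approx(
            sk.balanced_accuracy_score(y_true, y_pred)
        )
        assert m.f1 == pytest.approx(sk.f1_score(y_true, y_pred, pos_label="B"))

    def test_empty_input_raises(self):
        with pytest.raises(InvariantError):
            compute_metrics([], [], positive_class="A")

    def test_macro_average_for_three_classes(self):
        y_true = ["A", "A", "B", "B", "C", "C"]
        y_pred = ["A", "A", "B", "C", "C", "C"]
        m = compute_metrics(y_true, y_pred)
        # recalls: A=1, B=0.5, C=1 -> balanced accuracy 5/6
        assert m.balanced_accuracy == pytest.approx(5 / 6)
        assert m.ber == pytest.approx(1 / 6)


class TestLoocv:
    def test_separable_clusters_have_zero_ber(self):
        rng = np.random.default_rng(2)
        X, y = clustered_data(rng, 10, 4, sep=10.0)
        ber = loocv_ber_curve(X, y, 2)
        assert ber[0] == 0.0

    def test_permuted_labels_hover_at_half(self):
        rng = np.random.default_rng(3)
        X, y = clustered_data(rng, 6, 3, sep=10.0)
        bers = []
        for _ in range(20):
            perm = list(rng.permutation(y))
            if len(set(perm[:3])) < 1:
                continue
            try:
                bers.append(loocv_ber_curve(X, perm, 1)[0])
            except InvariantError:
                continue
        assert abs(np.mean(bers) - 0.5) < 0.15

    def test_ber_invariant_to_class_duplication(self):
        """For a fixed fitted rule, duplicating one class's samples leaves
        per-class error rates (hence BER) unchanged."""
        rng = np.random.default_rng(4)
        X, y = clustered_data(rng, 8, 3, sep=2.0)
        model = fit_plsda(X, y, 1)

        def ber_of(Xe, ye):
            pred, _ = predict_plsda(model, Xe)
            rates = []
            for c in ("A", "B"):
                idx = [i for i, label in enumerate(ye) if label == c]
                rates.append(np.mean([pred[i] != c for i in idx]))
            return np.mean(rates)

        base = ber_of(X, y)
        X_dup = np.vstack([X, X[:8]])
        y_dup = y + ["A"] * 8
        assert ber_of(X_dup, y_dup) == pytest.approx(base, abs=1e-12)

    def test_tiny_class_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(InvariantError):
            loocv_ber_curve(X, ["A", "A", "B", "B", "B", "B"], 1)


class TestReplicatedEvaluation:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        X, y = clustered_data(rng, 8, 5, sep=3.0)
        a = replicated_evaluation(X, y, n_replicates=4, seed=7)
        b = replicated_evaluation(X, y, n_replicates=4, seed=7)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        np.testing.assert_array_equal(a.vip_by_replicate, b.vip_by_replicate)

    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(6)
        X, y = clustered_data(rng, 10, 4, sep=12.0)
        report = replicated_evaluation(X, y, n_replicates=10, seed=1)
        assert report.aggregate.loc["accuracy", "mean"] == pytest.approx(1.0)
        assert report.aggregate.loc["accuracy", "sd"] == pytest.approx(0.0)

    def test_null_data_accuracy_in_chance_band(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 6))
        y = ["A"] * 12 + ["B"] * 12
        report = replicated_evaluation(X, y, n_replicates=10, seed=2)
        assert 0.25 <= report.aggregate.loc["accuracy", "mean"] <= 0.75

    def test_small_class_raises(self):
        X = np.random.default_rng(0).normal(size=(7, 3))
        with pytest.raises(InvariantError):
            replicated_evaluation(X, ["A"] * 3 + ["B"] * 4, n_replicates=2)

    def test_bad_train_fraction_raises(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        y = ["A"] * 6 + ["B"] * 6
        with pytest.raises(InvariantError):
            replicated_evaluation(X, y, train_fraction=1.2)

    def test_vip_table_flags_discriminator(self):
        """The variable carrying the class difference tops the VIP table."""
        rng = np.random.default_rng(9)
        X = rng.normal(scale=0.3, size=(20, 5))
        X[10:, 2] += 4.0
        y = ["A"] * 10 + ["B"] * 10
        report = replicated_evaluation(X, y, n_replicates=5, seed=3)
        table = report.vip_table()
        assert table.iloc[0]["variable"] == "v2"
        assert bool(table.iloc[0]["vip_gt_1"])


class TestUnivariate:
    def test_bh_stepup_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=12)
        adj = bh_adjust(p)
        # brute force: adj_(i) = min_{j>=i} p_(j) * m / j on sorted p
        order = np.argsort(p)
        m = len(p)
        sorted_adj = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        sorted_adj = np.minimum(sorted_adj, 1.0)
        expected = np.empty(m)
        expected[order] = sorted_adj
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_two_groups_use_t_test(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 4))
        res = univariate_screen(X, ["A"] * 6 + ["B"] * 6)
        assert set(res.table["test_used"]) == {"t_test"}
        assert res.pairwise is None

    def test_three_groups_use_anova_tukey(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 3))
        res = univariate_screen(X, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        assert set(res.table["test_used"]) == {"anova_tukey"}
        assert res.pairwise is not None
        assert len(res.pairwise) == 3 * 3  # 3 pairs per variable

    def test_shapiro_reported_per_group(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 2))
        res = univariate_screen(X, ["A"] * 5 + ["B"] * 5)
        assert "shapiro_W_A" in res.table.columns
        assert "shapiro_p_B" in res.table.columns

    def test_strong_shift_found_significant(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 5))
        X[10:, 1] += 5.0
        res = univariate_screen(X, ["A"] * 10 + ["B"] * 10)
        assert bool(res.table.loc[res.table["variable"] == "v1", "significant"].iloc[0])

    def test_small_group_raises(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(InvariantError):
            univariate_screen(X, ["A", "A", "B", "B", "B"])

    def test_null_rarely_flags_fixed_variable(self):
        rng = np.random.default_rng(15)
        flagged = 0
        n_sim = 40
        for _ in range(n_sim):
            X = rng.normal(size=(12, 6))
            res = univariate_screen(X, ["A"] * 6 + ["B"] * 6)
            flagged += bool(res.table["significant"].iloc[0])
        assert flagged / n_sim <= 0.10


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=20)
)
def test_bh_monotonicity_properties(pvals):
    adj = bh_adjust(pvals)
    p = np.asarray(pvals)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0 + 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
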