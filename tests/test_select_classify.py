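"""Standardization, L1-penalized selection, weighted SVM and metrics."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from neurofuse.select_classify import (
    DEFAULT_SVM_GRID,
    SvmFit,
    apply_standardizer,
    compute_metrics,
    default_lambda_grid,
    fit_standardizer,
    inverse_frequency_weights,
    lambda_max,
    lasso_objective,
    lasso_select,
    predict,
    svm_primal_objective,
    sweep_alpha,
    train_svm,
)


class TestStandardizer:
    def test_training_columns_become_zero_mean_unit_sd(self, rng):
        X = rng.normal(5.0, 3.0, size=(40, 6))
        std = fit_standardizer(X)
        Z = apply_standardizer(std, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_hand_computed_transform_of_test_point(self):
        std = fit_standardizer(np.array([[2.0], [4.0]]))
        assert std.mean[0] == pytest.approx(3.0)
        assert std.sd[0] == pytest.approx(1.0)  # population convention
        assert apply_standardizer(std, np.array([[5.0]]))[0, 0] == pytest.approx(2.0)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.arange(4.0), np.full(4, 9.0)])
        Z = apply_standardizer(fit_standardizer(X), X)
        assert np.all(Z[:, 1] == 0.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((1, 3)))

    def test_test_statistics_never_used(self, rng):
        """The transform of held-out data depends only on training statistics."""
        train = rng.normal(size=(20, 3))
        std = fit_standardizer(train)
        test_a = rng.normal(size=(5, 3))
        Z_alone = apply_standardizer(std, test_a)
        Z_joint = apply_standardizer(std, np.vstack([test_a, rng.normal(100, 50, size=(5, 3))]))
        np.testing.assert_array_equal(Z_alone, Z_joint[:5])


class TestLassoObjective:
    def test_zero_coefficients_give_half_label_norm(self):
        X = np.ones((4, 2))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert lasso_objective(np.zeros(2), X, y, lam=1.0) == pytest.approx(2.0)

    def test_least_squares_solution_zeroes_residual_term(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        theta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ theta
        assert lasso_objective(theta, X, y, lam=0.0) == pytest.approx(0.5 * resid @ resid, abs=1e-10)

    def test_soft_threshold_minimizer_matches_grid(self):
        # single feature, X = [1, 1]^T, y = (1, 1): theta* = max(0, 1 - lam/2)
        X = np.array([[1.0], [1.0]])
        y = np.array([1.0, 1.0])
        for lam in (0.5, 1.0, 3.0):
            expected_theta = max(0.0, 1.0 - lam / 2.0)
            grid = np.linspace(-2, 2, 400001)
            grid_vals = 0.5 * ((y[0] - grid) ** 2 + (y[1] - grid) ** 2) + lam * np.abs(grid)
            fit = lasso_select(X, y, lam)
            assert fit.theta[0] == pytest.approx(expected_theta, abs=1e-8)
            assert lasso_objective(fit.theta, X, y, lam) == pytest.approx(grid_vals.min(), abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dims"):
            lasso_objective(np.zeros(3), np.ones((4, 2)), np.ones(4), 1.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            lasso_objective(np.zeros(2), np.ones((4, 2)), np.ones(4), -1.0)


class TestLassoSelect:
    def test_lambda_above_threshold_empties_support(self, rng):
        X = rng.normal(size=(20, 8))
        y = np.sign(rng.normal(size=20))
        lam_max = lambda_max(X, y)
        assert lasso_select(X, y, lam_max).support.size == 0
        assert lasso_select(X, y, lam_max * 1.5).support.size == 0
        assert lasso_select(X, y, lam_max * 0.5).support.size > 0

    def test_planted_support_recovered_exactly(self):
        rng = np.random.default_rng(42)
        n, d, k = 200, 50, 5
        X = rng.normal(size=(n, d))
        true_support = np.arange(k)
        beta = np.zeros(d)
        beta[true_support] = 5.0
        y = X @ beta + 0.1 * rng.normal(size=n)
        lam = 0.05 * lambda_max(X, y)
        fit = lasso_select(X, y, lam)
        np.testing.assert_array_equal(fit.support, true_support)

    def test_solution_beats_random_perturbations(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.sign(rng.normal(size=30))
        lam = 0.3 * lambda_max(X, y)
        fit = lasso_select(X, y, lam)
        best = lasso_objective(fit.theta, X, y, lam)
        assert best <= lasso_objective(np.zeros(10), X, y, lam)
        for _ in range(100):
            perturbed = fit.theta + rng.normal(scale=0.05, size=10)
            assert best <= lasso_objective(perturbed, X, y, lam) + 1e-9

    def test_small_instances_match_dense_grid_search(self, rng):
        """Solver minimum equals exhaustive grid search on d <= 3 problems."""
        for d in (1, 2, 3):
            X = rng.normal(size=(8, d))
            y = np.sign(rng.normal(size=8))
            lam = 0.4 * lambda_max(X, y)
            fit = lasso_select(X, y, lam)
            axes = [np.linspace(-1.5, 1.5, 151)] * d
            mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
            vals = 0.5 * ((y[None, :] - mesh @ X.T) ** 2).sum(axis=1) + lam * np.abs(mesh).sum(axis=1)
            assert lasso_objective(fit.theta, X, y, lam) <= vals.min() + 1e-4

    def test_support_size_monotone_in_lambda(self, rng):
        X = rng.normal(size=(40, 15))
        y = np.sign(rng.normal(size=40))
        sizes = [lasso_select(X, y, lam).support.size for lam in default_lambda_grid(X, y, 12)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_agrees_with_reference_solver(self, rng):
        """Coordinate descent matches the established solver (alpha = lam / N)."""
        X = rng.normal(size=(50, 12))
        y = X @ np.array([2.0, -1.5] + [0.0] * 10) + 0.05 * rng.normal(size=50)
        lam = 0.1 * lambda_max(X, y)
        ours = lasso_select(X, y, lam)
        reference = Lasso(alpha=lam / len(y), fit_intercept=False, tol=1e-10, max_iter=50000).fit(X, y)
        np.testing.assert_allclose(ours.theta, reference.coef_, atol=1e-6)


class TestSweepAlpha:
    def _toy(self, rng, n=40, d=20):
        X = rng.normal(size=(n, d))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        return X, y.astype(int)

    def test_single_element_grid_returned(self, rng):
        X, y = self._toy(rng)
        lam, curve = sweep_alpha(X, y, lam_grid=[0.5 * lambda_max(X, y)], seed=0)
        assert lam == pytest.approx(0.5 * lambda_max(X, y))
        assert len(curve) == 1

    def test_curve_has_one_row_per_grid_value(self, rng):
        X, y = self._toy(rng)
        grid = default_lambda_grid(X, y, 6)
        _, curve = sweep_alpha(X, y, lam_grid=grid, seed=0)
        assert len(curve) == 6
        assert curve["retained"].dtype == bool

    def test_argmax_matches_exhaustive_re_evaluation(self, rng):
        X, y = self._toy(rng)
        best, curve = sweep_alpha(X, y, n_lambdas=8, seed=3)
        retained = curve[curve["retained"]]
        top = retained[retained["accuracy"] == retained["accuracy"].max()]
        # ties break toward the larger (sparser) lam
        assert best == pytest.approx(top["lam"].max())

    def test_overfit_guard_can_discard_everything(self, rng):
        X, y = self._toy(rng)
        with pytest.raises(ValueError, match="discarded"):
            sweep_alpha(X, y, n_lambdas=4, max_features=0, seed=0)


class TestSvm:
    def test_separable_points_perfectly_fit(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array([-1, 1])
        fit = train_svm(X, y, grid=({"kernel": "linear", "C": 1.0},))
        labels, _ = predict(fit, X)
        np.testing.assert_array_equal(labels, y)

    def test_xor_needs_nonlinear_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        rbf = train_svm(X, y, grid=({"kernel": "rbf", "C": 100.0, "gamma": "scale"},))
        assert (predict(rbf, X)[0] == y).all()
        linear = train_svm(X, y, grid=({"kernel": "linear", "C": 100.0},))
        assert (predict(linear, X)[0] == y).mean() <= 0.75

    def test_predictions_are_signs_of_scores(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] > 0, 1, -1)
        fit = train_svm(X, y, grid=DEFAULT_SVM_GRID[:4], seed=0)
        labels, scores = predict(fit, rng.normal(size=(10, 4)))
        assert set(np.unique(labels)).issubset({-1, 1})
        np.testing.assert_array_equal(labels, np.where(scores >= 0, 1, -1))

    def test_zero_score_maps_to_positive_class(self):
        class _Zero:
            def decision_function(self, X):
                return np.zeros(len(X))

        fit = SvmFit(estimator=_Zero(), kernel="linear", C=1.0, gamma="scale", class_weights={}, n_features=2)
        labels, scores = predict(fit, np.zeros((3, 2)))
        assert np.all(labels == 1)
        assert np.all(scores == 0)

    def test_hard_margin_decision_values(self):
        X = np.array([[-2.0, 0.0], [-1.5, 1.0], [2.0, 0.0], [1.5, -1.0]])
        y = np.array([-1, -1, 1, 1])
        fit = train_svm(X, y, grid=({"kernel": "linear", "C": 1e6},), class_weights={-1: 0.5, 1: 0.5})
        _, scores = predict(fit, X)
        assert np.all(y * scores >= 1.0 - 1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_svm(np.ones((4, 2)), np.ones(4))

    def test_inverse_frequency_weights_for_imbalanced_cohort(self):
        y = np.array([1] * 70 + [-1] * 50)
        weights = inverse_frequency_weights(y)
        assert weights[1] == pytest.approx(50 / 120)
        assert weights[-1] == pytest.approx(70 / 120)

    def test_trained_objective_beats_random_feasible_points(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
        c = 1.0
        fit = train_svm(X, y, grid=({"kernel": "linear", "C": c},), class_weights={-1: 1.0, 1: 1.0})
        w = fit.estimator.coef_[0]
        b = float(fit.estimator.intercept_[0])
        trained = svm_primal_objective(w, b, X, y, c)
        for _ in range(50):
            w_r = rng.normal(scale=np.abs(w).max() + 1.0, size=3)
            b_r = rng.normal()
            assert trained <= svm_primal_objective(w_r, b_r, X, y, c) + 1e-6


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 1, -1, -1])
        m = compute_metrics(y, y, scores=np.array([2.0, 1.0, -1.0, -2.0]))
        assert m == {"ACC": 100.0, "SEN": 100.0, "SPE": 100.0, "AUC": 100.0}

    def test_hand_counted_confusion_table(self):
        y_true = np.array([1, 1, 1, -1, -1])
        y_pred = np.array([1, -1, 1, -1, 1])
        m = compute_metrics(y_true, y_pred)
        assert m["ACC"] == pytest.approx(60.0)
        assert m["SEN"] == pytest.approx(100 * 2 / 3)
        assert m["SPE"] == pytest.approx(50.0)

    def test_constant_scores_give_chance_auc(self):
        y = np.array([1, -1, 1, -1])
        m = compute_metrics(y, y, scores=np.zeros(4))
        assert m["AUC"] == pytest.approx(50.0)

    def test_relabeling_swaps_sen_spe_keeps_acc(self, rng):
        y_true = np.where(rng.normal(size=50) > 0.3, 1, -1)
        y_pred = np.where(rng.normal(size=50) > 0.0, 1, -1)
        m_pos = compute_metrics(y_true, y_pred, positive=1)
        m_neg = compute_metrics(y_true, y_pred, positive=-1)
        assert m_pos["ACC"] == pytest.approx(m_neg["ACC"])
        assert m_pos["SEN"] == pytest.approx(m_neg["SPE"])
        assert m_pos["SPE"] == pytest.approx(m_neg["SEN"])

    def test_auc_invariant_to_monotone_transform(self, rng):
        y = np.where(rng.normal(size=40) > 0, 1, -1)
        scores = rng.normal(size=40)
        a = compute_metrics(y, y, scores=scores)["AUC"]
        b = compute_metrics(y, y, scores=np.exp(3 * scores) + 7)["AUC"]
        assert a == pytest.approx(b)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(np.ones(4), np.ones(4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_metrics(np.ones(4), np.ones(3))
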