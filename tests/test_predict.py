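"""LDA/MLR fits against closed forms and independent implementations,
exactness of the fast LOOCV paths, SFFS behavior, and the evaluation
metrics."""

import warnings

import numpy as np
import pytest

from oscipain.core import FREQ_GRID, CohortFeatures
from oscipain.errors import FitError, FoldError, ParameterError
from oscipain.predict import (
    PredictionResult,
    evaluate,
    lda_fit,
    loocv,
    mlr_fit,
    sffs,
    single_feature_maps,
)


class TestLDA:
    def test_one_dimensional_boundary_at_midpoint(self):
        X = np.array([[1.0], [2.0], [5.0], [6.0]])
        y = np.array([0, 0, 1, 1])
        model = lda_fit(X, y, reg=1e-6)
        assert model.predict(np.array([[3.0]]))[0] == 0
        assert model.predict(np.array([[4.0]]))[0] == 1
        # boundary sits where the decision function crosses zero: 3.5
        root = -model.bias / model.weights[0]
        assert root == pytest.approx(3.5, abs=1e-6)

    def test_identical_class_means_fall_back_to_prior(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([0, 0, 1, 1, 1, 1])
        model = lda_fit(X, y)
        assert np.allclose(model.weights, 0.0)
        assert model.predict(X).tolist() == [1] * 6  # majority class

    def test_absent_class_rejected(self):
        with pytest.raises(FitError):
            lda_fit(np.zeros((4, 2)), np.zeros(4))

    def test_well_separated_2d_toy_matches_independent_lda(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((200, 2)) + [0, 0],
                       rng.standard_normal((200, 2)) + [4, 3]])
        y = np.repeat([0, 1], 200)
        ours = lda_fit(X, y, reg=1e-9)
        acc = np.mean(ours.predict(X) == y)
        assert acc > 0.99
        ref = sklearn_lda(solver="lsqr").fit(X, y)
        assert np.mean(ref.predict(X) == y) == pytest.approx(acc, abs=0.01)
        # direction of the weight vector agrees with the reference
        cos = np.dot(ours.weights, ref.coef_[0]) / (
            np.linalg.norm(ours.weights) * np.linalg.norm(ref.coef_[0]))
        assert cos > 0.999


class TestMLR:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 4))
        y = 3.0 * X[:, 2] + 1.5
        model = mlr_fit(X, y)
        assert model.coefficients[2] == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(np.delete(model.coefficients, 2), 0.0, atol=1e-8)
        assert model.intercept == pytest.approx(1.5, abs=1e-8)

    def test_zero_design_gives_intercept_only(self):
        y = np.array([1.0, 2.0, 6.0])
        model = mlr_fit(np.zeros((3, 5)), y)
        assert model.intercept == pytest.approx(y.mean())
        assert np.allclose(model.coefficients, 0.0)

    def test_least_squares_optimality_against_perturbations(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(30)
        model = mlr_fit(X, y)
        beta = np.concatenate([[model.intercept], model.coefficients])
        Z = np.column_stack([np.ones(30), X])
        best = np.sum((y - Z @ beta) ** 2)
        for _ in range(1000):
            trial = beta + rng.normal(0, 0.05, size=beta.shape)
            assert np.sum((y - Z @ trial) ** 2) >= best - 1e-9

    def test_residuals_orthogonal_to_features(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        model = mlr_fit(X, y)
        resid = y - model.predict(X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)


class TestLoocv:
    def test_fast_lda_path_equals_explicit_refits(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 7))
        y = (rng.random(40) > 0.4).astype(int)
        y[:2] = [0, 1]
        fast = loocv(X, y, "lda", fast=True)
        slow = loocv(X, y, "lda", fast=False)
        assert np.array_equal(fast.y_pred, slow.y_pred)

    def test_fast_mlr_path_equals_explicit_refits(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        fast = loocv(X, y, "mlr", fast=True)
        slow = loocv(X, y, "mlr", fast=False)
        assert np.allclose(fast.y_pred, slow.y_pred, atol=1e-8)

    def test_predictions_invariant_to_subject_order(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 4))
        y = np.tile([0, 1], 10)
        perm = rng.permutation(20)
        a = loocv(X, y, "lda")
        b = loocv(X[perm], y[perm], "lda")
        assert np.array_equal(a.y_pred[perm], b.y_pred)

    def test_single_member_class_surfaces_subject_id(self):
        X = np.zeros((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(FoldError, match="s0"):
            loocv(X, y, "lda")

    def test_permuted_labels_stay_in_chance_band(self):
        """Null: label permutations give mean accuracy within the 95%
        binomial band around the majority-class rate."""
        rng = np.random.default_rng(3)
        n = 30
        X = rng.standard_normal((n, 3))
        base = np.array([0] * 15 + [1] * 15)
        accs = [
            loocv(X, rng.permutation(base), "lda").accuracy for _ in range(100)
        ]
        majority = 0.5
        band = 1.96 * np.sqrt(majority * (1 - majority) / n)
        assert abs(np.mean(accs) - majority) < band


class TestEvaluate:
    def test_67_fold_run_with_5_errors_prints_9254(self):
        y_true = np.array([1] * 33 + [0] * 34)
        y_pred = y_true.copy()
        y_pred[[0, 5, 10, 40, 60]] ^= 1
        result = PredictionResult([f"s{i}" for i in range(67)], y_true, y_pred, "lda")
        report = evaluate(result)
        assert report.accuracy_pct == 92.54
        assert report.n_errors == 5

    def test_perfect_predictions(self):
        y = np.arange(10.0)
        res = PredictionResult([f"s{i}" for i in range(10)], y, y.copy(), "mlr")
        assert evaluate(res).pearson_r == pytest.approx(1.0)

    def test_shifted_predictions_still_r_one(self):
        y = np.arange(10.0)
        res = PredictionResult([f"s{i}" for i in range(10)], y, y + 3.0, "mlr")
        assert evaluate(res).pearson_r == pytest.approx(1.0)

    def test_anticorrelated_predictions(self):
        y = np.arange(10.0)
        res = PredictionResult([f"s{i}" for i in range(10)], y, -y, "mlr")
        assert evaluate(res).pearson_r == pytest.approx(-1.0)

    def test_constant_predictions_flagged(self):
        y = np.arange(10.0)
        res = PredictionResult([f"s{i}" for i in range(10)], y, np.ones(10), "mlr")
        assert evaluate(res).constant_predictions


class TestSingleFeatureMaps:
    def test_focal_fcz_gamma_plant_localizes_exactly(self):
        """A signal confined to the (FCz, gamma) cells of the grid puts the
        profile maxima at FCz and inside 31-50 Hz."""
        rng = np.random.default_rng(8)
        electrodes = ["Fz", "FCz", "Cz", "Pz"]
        freqs = FREQ_GRID.tolist()
        index = [(e, f) for e in electrodes for f in freqs]
        n = 40
        y = np.tile([0, 1], n // 2)
        X = rng.standard_normal((n, len(index)))
        for j, (e, f) in enumerate(index):
            if e == "FCz" and 31.0 <= f <= 50.0:
                X[:, j] += 1.8 * y
        feats = CohortFeatures([f"s{i}" for i in range(n)], index, X)
        maps = single_feature_maps(feats, groups=y, ratings=y + 0.1 * rng.standard_normal(n))
        assert maps["electrode_accuracy"].idxmax() == "FCz"
        assert 31.0 <= maps["frequency_accuracy"].idxmax() <= 50.0
        assert maps["electrode_r"].idxmax() == "FCz"
        assert 31.0 <= maps["frequency_r"].idxmax() <= 50.0

    def test_simulated_gamma_cohort_localizes_to_frontocentral(self, gamma_only_cohort):
        from oscipain.montage import FRONTOCENTRAL

        features, metas = gamma_only_cohort
        groups = [m.group for m in metas]
        maps = single_feature_maps(features, groups=groups)
        assert maps["electrode_accuracy"].idxmax() in FRONTOCENTRAL
        assert 31.0 <= maps["frequency_accuracy"].idxmax() <= 50.0
        # FCz is at worst a whisker behind the cluster maximum
        assert maps["electrode_accuracy"]["FCz"] >= maps["electrode_accuracy"].max() - 0.06

    def test_degenerate_single_cell_grid(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 1))
        y = (X[:, 0] > 0).astype(int)
        feats = CohortFeatures([f"s{i}" for i in range(12)], [("Cz", 10.0)], X)
        maps = single_feature_maps(feats, groups=y)
        expected = loocv(X, y, "lda").accuracy
        assert maps["electrode_accuracy"].tolist() == [expected]
        assert maps["frequency_accuracy"].tolist() == [expected]


class TestSFFS:
    def test_single_informative_feature_selected_alone(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 6))
        y = np.tile([0, 1], 12)
        X[:, 3] = y * 2.0 - 1.0  # perfectly determines the label
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace, result = sffs(X, y, "lda")
        assert trace.selected == [3]
        assert trace.stop_reason == "no_improvement"
        assert result.accuracy == 1.0

    def test_criterion_trace_is_strictly_improving(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 25))
        y = rng.standard_normal(30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace, _ = sffs(X, y, "mlr", max_k=10)
        values = [v for _, _, v in trace.history]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert len(trace.selected) <= 10

    def test_weak_feature_cohort_reaches_the_cap(self):
        from oscipain.simulate import simulate_weak_feature_cohort

        X, ratings, _ = simulate_weak_feature_cohort(n_subjects=40, n_features=120,
                                                     seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace, _ = sffs(X, ratings, "mlr", max_k=20)
        assert len(trace.selected) == 20
        assert trace.stop_reason == "max_k"

    def test_undefined_criterion_candidates_skipped(self):
        # constant outcome -> LOOCV correlation undefined for every candidate
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 4))
        y = np.full(10, 3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace, _ = sffs(X, y, "mlr")
        assert trace.selected == []
        assert trace.stop_reason == "no_improvement"

    def test_nonnested_leakage_warning_emitted(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((16, 5))
        y = np.tile([0, 1], 8)
        with pytest.warns(UserWarning, match="biased"):
            sffs(X, y, "lda", max_k=2)

    def test_empty_feature_matrix_rejected(self):
        with pytest.raises(ParameterError):
            sffs(np.zeros((10, 0)), np.arange(10.0), "mlr")
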