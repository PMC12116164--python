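"""Feature screening, model fits and the R^2/RMSE evaluation formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardfusion.fusion import (FEATURE_SETS, aggregate_spad, build_feature_matrix,
                                  compute_plot_yield, correlation_table, evaluate,
                                  evaluate_grid, fit_and_predict, pearson,
                                  select_features, split_records)
from orchardfusion.synthetic import DEFAULT_BETA, generate_plot_dataset

# A published-style correlation screening profile: |r| of each candidate
# feature against plot yield.  Under the default group rules (SPAD and
# multispectral |r|>0.6, structural |r|>0.7, single best visible index,
# GNDVI excluded) this selects the canonical ten-feature fused set.
REFERENCE_CORRELATIONS = {
    "s1": 0.702, "s2": 0.689,
    "MGRVI": 0.445, "RGBVI": 0.186, "EXR": 0.245, "NDI": 0.353,
    "VARI": 0.755, "EXG": 0.423, "EXGR": 0.024, "GLI": 0.437,
    "DVI": 0.687, "GDVI": 0.642, "GEVI": 0.602, "NDVI": 0.398,
    "GRVI": 0.501, "GNDVI": 0.742, "EVI": 0.429, "RVI": 0.505,
    "f1": 0.792, "f2": 0.750, "f3": 0.740, "f4": 0.800,
}


class TestFieldAggregation:
    def test_constant_tree(self):
        assert aggregate_spad([[40] * 6]) == 40

    def test_plot_mean_over_trees(self):
        trees = [[40] * 6, [42] * 6, [44] * 6]
        assert aggregate_spad(trees) == 42

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 5))
    def test_matches_bruteforce_nested_mean(self, seed, n_trees):
        rng = np.random.default_rng(seed)
        trees = rng.uniform(20, 60, size=(n_trees, 6))
        expected = sum(sum(t) / 6 for t in trees.tolist()) / n_trees
        assert aggregate_spad(trees) == pytest.approx(expected, abs=1e-12)

    def test_wrong_leaf_count_raises(self):
        with pytest.raises(ValueError):
            aggregate_spad([[40] * 5])

    def test_plot_yield_product(self):
        assert compute_plot_yield(80, 0.25, 20) == 400.0
        assert compute_plot_yield(0, 0.25) == 0.0
        with pytest.raises(ValueError):
            compute_plot_yield(-1, 0.25)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0, 500), st.floats(0, 1), st.integers(0, 40))
    def test_yield_equals_product_oracle(self, count, weight, trees):
        assert compute_plot_yield(count, weight, trees) == count * weight * trees


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_definition_formula(self):
        x, y = np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 5.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestScreening:
    def test_toy_threshold(self):
        out = select_features({"s1": 0.9, "s2": 0.1},
                              rules={"spad": {"threshold": 0.6}})
        assert out == ["s1"]

    def test_zero_threshold_returns_everything(self):
        corr = {"s1": 0.1, "f1": -0.05, "DVI": 0.2}
        out = select_features(corr, rules={"spad": {"threshold": 0.0},
                                           "structural": {"threshold": 0.0},
                                           "multispectral": {"threshold": 0.0}})
        assert out == ["s1", "f1", "d1"]

    def test_reference_profile_reproduces_fused_feature_set(self):
        out = select_features(REFERENCE_CORRELATIONS)
        assert out == FEATURE_SETS["G"]

    def test_unknown_feature_group_raises(self):
        with pytest.raises(KeyError):
            select_features({"mystery": 0.5})


class TestMatricesAndSplits:
    def test_feature_set_structure(self):
        assert len(FEATURE_SETS["G"]) == 10
        assert set(FEATURE_SETS["E"]) & set(FEATURE_SETS["F"]) == {"d1", "d2", "d3", "k1"}

    def test_matrix_shapes_and_order(self):
        plots = generate_plot_dataset(80, seed=0)
        X, y = build_feature_matrix(plots, "A")
        assert X.shape == (80, 2) and y.shape == (80,)
        XG, _ = build_feature_matrix(plots, "G")
        assert XG.shape == (80, 10)
        assert np.array_equal(XG[:, 0], X[:, 0])   # s1 leads both

    def test_missing_column_error_names_it(self):
        import pandas as pd
        df = pd.DataFrame({"s1": [1.0], "yield_kg": [2.0]})
        with pytest.raises(KeyError, match="s2"):
            build_feature_matrix(df, "A")

    @pytest.mark.parametrize("m,expected_train", [(80, 56), (10, 7), (20, 14)])
    def test_split_sizes(self, m, expected_train):
        plots = generate_plot_dataset(m, seed=1)
        train, test = split_records(plots, seed=0)
        assert len(train) == expected_train and len(test) == m - expected_train

    def test_split_deterministic_disjoint_exhaustive(self):
        plots = generate_plot_dataset(40, seed=2)
        t1 = split_records(plots, seed=5)
        t2 = split_records(plots, seed=5)
        assert t1[0]["plot_id"].tolist() == t2[0]["plot_id"].tolist()
        ids = set(t1[0]["plot_id"]) | set(t1[1]["plot_id"])
        assert len(ids) == 40
        assert not set(t1[0]["plot_id"]) & set(t1[1]["plot_id"])

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            split_records(generate_plot_dataset(8, seed=0))


@pytest.fixture(scope="module")
def noise_free():
    plots = generate_plot_dataset(80, noise_sd=0.0, seed=1)
    return split_records(plots, seed=0)


class TestModels:
    def test_pls_is_near_perfect_on_linear_data(self, noise_free):
        train, test = noise_free
        _, yhat, _ = fit_and_predict("PLS", train, test, "G", seed=0,
                                     hyperparams={"n_components": 10})
        assert evaluate(test["yield_kg"], yhat).r2 >= 0.999

    def test_pls_recovers_generative_coefficients(self, noise_free):
        train, test = noise_free
        _, _, est = fit_and_predict("PLS", train, test, "G", seed=0,
                                    hyperparams={"n_components": 10})
        beta_hat = est.named_steps["model"].coef_.ravel() / est.named_steps["scale"].scale_
        assert np.abs(beta_hat - DEFAULT_BETA).max() < 1e-6

    def test_knn_with_k1_memorises_training_targets(self, noise_free):
        train, test = noise_free
        yhat_train, _, _ = fit_and_predict("KNN", train, test, "G", seed=0,
                                           hyperparams={"n_neighbors": 1})
        assert np.allclose(yhat_train, train["yield_kg"], atol=1e-12)

    def test_knn_k_larger_than_train_raises(self, noise_free):
        train, test = noise_free
        with pytest.raises(ValueError):
            fit_and_predict("KNN", train, test, "G",
                            hyperparams={"n_neighbors": 100})

    def test_unknown_model_raises(self, noise_free):
        train, test = noise_free
        with pytest.raises(ValueError):
            fit_and_predict("MLP", train, test, "G")

    def test_svm_predictions_match_manual_kernel_evaluation(self, noise_free):
        """Re-evaluate the fitted RBF machine from its support vectors."""
        train, test = noise_free
        hp = {"C": 100.0, "gamma": 0.5, "epsilon": 0.1}
        _, yhat_test, est = fit_and_predict("SVM", train, test, "G",
                                            hyperparams=hp, seed=0)
        scaler, svr = est.named_steps["scale"], est.named_steps["model"]
        X_test, _ = build_feature_matrix(test, "G")
        Z = scaler.transform(X_test)
        sv = svr.support_vectors_
        d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        manual = np.exp(-hp["gamma"] * d2) @ svr.dual_coef_.ravel() + svr.intercept_[0]
        assert np.abs(manual - yhat_test).max() < 1e-9

    def test_svm_accuracy_on_noisy_synthetic_plots(self):
        plots = generate_plot_dataset(80, noise_sd=5.0, seed=7)
        train, test = split_records(plots, seed=7)
        _, yhat, _ = fit_and_predict("SVM", train, test, "G", seed=7)
        assert evaluate(test["yield_kg"], yhat).r2 >= 0.9


class TestEvaluate:
    def test_perfect_prediction(self):
        res = evaluate([1, 2, 3], [1, 2, 3])
        assert res.r2 == 1.0 and res.rmse == 0.0

    def test_hand_arithmetic_case(self):
        res = evaluate([1, 2, 3], [1, 2, 4])
        assert res.r2 == pytest.approx(0.5)
        assert res.rmse == pytest.approx(np.sqrt(1 / 3))

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2, 3, 4])
        res = evaluate(y, np.full(4, y.mean()))
        assert res.r2 == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_target_raises(self):
        with pytest.raises(ValueError):
            evaluate([2, 2, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 40))
    def test_matches_direct_formula_on_random_vectors(self, seed, m):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=m)
        yhat = rng.normal(size=m)
        res = evaluate(y, yhat)
        ss_res = sum((b - a) ** 2 for a, b in zip(y, yhat))
        ss_tot = sum((np.mean(y) - a) ** 2 for a in y)
        assert abs(res.r2 - (1 - ss_res / ss_tot)) < 1e-12
        assert abs(res.rmse - np.sqrt(ss_res / m)) < 1e-12
        # R^2 = 1 iff RMSE = 0 on the same sample
        assert (res.r2 == 1.0) == (res.rmse == 0.0)


def test_grid_covers_every_cell():
    plots = generate_plot_dataset(30, noise_sd=2.0, seed=3)
    grid = evaluate_grid(plots, feature_sets=("A", "B"), models=("KNN", "PLS"),
                         seed=0)
    assert len(grid) == 2 * 2 * 2
    assert set(grid["split"]) == {"train", "test"}
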