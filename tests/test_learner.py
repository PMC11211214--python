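import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from epspec import learner
from epspec.config import HyperParamBounds
from epspec.evaluate import average_precision


def _planted(n=2000, n_causal=3, n_noise=10, prevalence=0.2, seed=0, beta=2.0):
    """Logistic labels driven by the first ``n_causal`` columns."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.random((n, n_causal + n_noise)),
        columns=[f"causal{i}" for i in range(n_causal)]
        + [f"noise{i}" for i in range(n_noise)],
    )
    logit = beta * X.iloc[:, :n_causal].sum(axis=1) - beta * n_causal / 2
    logit += np.log(prevalence / (1 - prevalence))
    y = (rng.random(n) < expit(logit)).astype(int)
    return X, y


class TestScaler:
    def test_train_column_maps_to_unit_interval(self):
        X = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        scaler, out = learner.scale_unit_interval(X, X.index)
        assert np.allclose(out["a"], [0.0, 0.5, 1.0])

    def test_unseen_values_not_clipped(self):
        X = pd.DataFrame({"a": [2.0, 4.0, 6.0, 8.0]})
        scaler, out = learner.scale_unit_interval(X, pd.Index([0, 1, 2]))
        assert out["a"].iloc[3] == pytest.approx(1.5)

    def test_constant_column_maps_to_zero(self):
        X = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        _, out = learner.scale_unit_interval(X, X.index)
        assert (out["a"] == 0).all()

    def test_statistics_come_from_fit_rows_only(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 100.0]})
        scaler, _ = learner.scale_unit_interval(X, pd.Index([0, 1]))
        assert scaler.mins["a"] == 0.0 and scaler.ranges["a"] == 1.0


class TestTraining:
    def _separable(self, n=200):
        X = pd.DataFrame({"f": np.r_[np.ones(n // 2), np.zeros(n // 2)]})
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        return X, y

    def test_separable_toy_reaches_perfect_training_ap(self):
        X, y = self._separable()
        bundle = learner.train_model(X, y, {"max_depth": 2, "n_rounds": 20})
        ap = average_precision(learner.predict_scores(bundle, X), y)
        assert ap == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = _planted(500)
        b1 = learner.train_model(X, y, {"max_depth": 3, "n_rounds": 30}, seed=5)
        b2 = learner.train_model(X, y, {"max_depth": 3, "n_rounds": 30}, seed=5)
        assert np.array_equal(
            learner.predict_scores(b1, X), learner.predict_scores(b2, X)
        )

    def test_early_stopping_round_within_budget(self):
        X, y = _planted(800, seed=2)
        val_X, val_y = _planted(300, seed=3)
        bundle = learner.train_model(
            X, y, {"max_depth": 3, "n_rounds": 300},
            X_val=val_X, y_val=val_y, early_stop_rounds=10,
        )
        assert bundle.best_iteration <= 299

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="single class"):
            learner.train_model(X, np.array([0, 0]), {})


class TestPrediction:
    def test_positive_pattern_scores_higher(self):
        X = pd.DataFrame({"f": np.r_[np.ones(50), np.zeros(50)]})
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        bundle = learner.train_model(X, y, {"max_depth": 2, "n_rounds": 20})
        s = learner.predict_scores(bundle, pd.DataFrame({"f": [1.0, 0.0]}))
        assert s[0] > s[1]

    def test_empty_input_empty_scores(self):
        X, y = pd.DataFrame({"f": [1.0, 0.0]}), np.array([1, 0])
        bundle = learner.train_model(X, y, {"max_depth": 1, "n_rounds": 5})
        assert len(learner.predict_scores(bundle, X.iloc[:0])) == 0

    def test_extra_columns_ignored(self):
        X, y = _planted(300)
        bundle = learner.train_model(X, y, {"max_depth": 3, "n_rounds": 20})
        withextra = X.assign(junk=np.arange(len(X)))
        assert np.array_equal(
            learner.predict_scores(bundle, X), learner.predict_scores(bundle, withextra)
        )

    def test_missing_feature_named_in_error(self):
        X, y = _planted(300)
        bundle = learner.train_model(X, y, {"max_depth": 3, "n_rounds": 20})
        with pytest.raises(KeyError, match="causal0"):
            learner.predict_scores(bundle, X.drop(columns=["causal0"]))


class TestShap:
    def test_local_accuracy_against_margin(self):
        X, y = _planted(500)
        bundle = learner.train_model(X, y, {"max_depth": 4, "n_rounds": 50})
        shap = learner.shap_attributions(bundle, X)
        margins = bundle.booster.predict(
            learner._dmatrix(X[bundle.selected_features]), output_margin=True
        )
        total = shap.values.sum(axis=1).to_numpy() + shap.base_values
        assert np.abs(total - margins).max() < 1e-4

    def test_depth_one_single_tree_attributes_split_feature_only(self):
        X = pd.DataFrame({"split": np.r_[np.ones(100), np.zeros(100)], "other": 0.5})
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        bundle = learner.train_model(
            X, y, {"max_depth": 1, "learning_rate": 1.0, "n_rounds": 1}
        )
        shap = learner.shap_attributions(bundle, X)
        assert np.allclose(shap.values["other"], 0.0)
        assert not np.allclose(shap.values["split"], 0.0)

    def test_concatenation_row_counts(self):
        X, y = _planted(300)
        bundle = learner.train_model(X, y, {"max_depth": 3, "n_rounds": 10})
        parts = [
            learner.shap_attributions(bundle, X.iloc[:100]),
            learner.shap_attributions(bundle, X.iloc[100:]),
        ]
        combined = learner.concat_shap(parts)
        assert len(combined.values) == len(X)

    def test_ranking_by_hand_mean(self):
        m = learner.ShapMatrix(
            values=pd.DataFrame([[1.0, 0.0], [-1.0, 0.5]], columns=["f1", "f2"]),
            base_values=np.zeros(2),
        )
        ranked = learner.rank_features_by_mean_abs_shap(m)
        assert list(ranked.index) == ["f1", "f2"]
        assert ranked["f1"] == pytest.approx(1.0)
        assert ranked["f2"] == pytest.approx(0.25)

    def test_all_zero_attributions_stable_name_order(self):
        m = learner.ShapMatrix(
            values=pd.DataFrame(np.zeros((3, 3)), columns=["c", "a", "b"]),
            base_values=np.zeros(3),
        )
        assert list(learner.rank_features_by_mean_abs_shap(m).index) == ["a", "b", "c"]

    def test_disjoint_feature_sets_rejected(self):
        m1 = learner.ShapMatrix(pd.DataFrame({"a": [1.0]}), np.zeros(1))
        m2 = learner.ShapMatrix(pd.DataFrame({"b": [1.0]}), np.zeros(1))
        with pytest.raises(ValueError):
            learner.concat_shap([m1, m2])


class TestBoruta:
    def test_planted_causal_features_confirmed(self):
        """3 planted + 20 noise at n=5000: all 3 confirmed in 20 rounds."""
        X, y = _planted(n=5000, n_causal=3, n_noise=20, seed=1, beta=3.0)
        res = learner.boruta_select(X, y, seed=0, n_rounds=20)
        assert set(res.confirmed) >= {"causal0", "causal1", "causal2"}

    def test_pure_noise_rejected_in_most_seeds(self):
        rejected = 0
        for seed in range(10):
            X, y = _planted(n=600, n_causal=2, n_noise=6, seed=seed, beta=3.0)
            res = learner.boruta_select(
                X, y, seed=seed, n_rounds=20, num_boost_round=40
            )
            if "noise0" in res.rejected:
                rejected += 1
        assert rejected >= 8

    def test_single_causal_feature_selected(self):
        X, y = _planted(n=1000, n_causal=1, n_noise=3, seed=4, beta=4.0)
        res = learner.boruta_select(X, y, seed=0, n_rounds=10, num_boost_round=40)
        assert len(res.selected()) >= 1

    def test_too_few_rounds_rejected(self):
        X, y = _planted(200)
        with pytest.raises(ValueError):
            learner.boruta_select(X, y, n_rounds=3)


class TestTuning:
    def _folded(self, n=800, seed=0):
        X, y = _planted(n, seed=seed)
        inner = pd.Series(np.arange(n) % 2, index=X.index)
        return X, y, inner

    def test_budget_one_is_deterministic(self):
        X, y, inner = self._folded()
        p1, _ = learner.tune_hyperparams(X, y, inner, budget=1, seed=7, max_rounds_cap=50)
        p2, _ = learner.tune_hyperparams(X, y, inner, budget=1, seed=7, max_rounds_cap=50)
        assert p1 == p2

    def test_argmax_beats_or_matches_first_candidate(self):
        X, y, inner = self._folded(seed=3)
        _, trace = learner.tune_hyperparams(X, y, inner, budget=5, seed=1, max_rounds_cap=50)
        assert trace["mean_inner_ap"].max() >= trace["mean_inner_ap"].iloc[0]

    def test_returned_params_within_declared_bounds(self):
        X, y, inner = self._folded()
        bounds = HyperParamBounds()
        params, _ = learner.tune_hyperparams(
            X, y, inner, budget=3, seed=0, bounds=bounds, max_rounds_cap=50
        )
        assert bounds.max_depth[0] <= params["max_depth"] <= bounds.max_depth[1]
        assert bounds.learning_rate[0] <= params["learning_rate"] <= bounds.learning_rate[1]
        assert bounds.subsample[0] <= params["subsample"] <= bounds.subsample[1]

    def test_zero_budget_rejected(self):
        X, y, inner = self._folded()
        with pytest.raises(ValueError):
            learner.tune_hyperparams(X, y, inner, budget=0)


class TestLeakageInstrumentation:
    def test_poisoned_test_rows_do_not_change_fit(self):
        """Scaler and model fitted on training rows are bitwise identical
        when test rows are replaced by sentinels."""
        X, y = _planted(600, seed=9)
        train = pd.Index(range(0, 400))
        test = pd.Index(range(400, 600))
        X_poison = X.copy()
        X_poison.loc[test] = 999.0

        s1, X1 = learner.scale_unit_interval(X, train)
        s2, X2 = learner.scale_unit_interval(X_poison, train)
        pd.testing.assert_series_equal(s1.mins, s2.mins)
        pd.testing.assert_series_equal(s1.ranges, s2.ranges)

        b1 = learner.train_model(X1.loc[train], y[train], {"max_depth": 3, "n_rounds": 30}, seed=1)
        b2 = learner.train_model(X2.loc[train], y[train], {"max_depth": 3, "n_rounds": 30}, seed=1)
        assert np.array_equal(
            learner.predict_scores(b1, X1.loc[train]),
            learner.predict_scores(b2, X2.loc[train]),
        )
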