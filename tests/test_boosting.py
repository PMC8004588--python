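"""Boosted regression trees: greedy splitting, boosting dynamics, grid
search, importance, and a cross-check against an independent library
implementation."""

import numpy as np
import pandas as pd
import pytest

import volqsrr as v
from volqsrr.boosting import BoostedTreesRegressor, fit_tree


class TestFitTree:
    def test_constant_target_single_leaf(self, rng):
        X = rng.normal(size=(20, 3))
        t = fit_tree(X, np.full(20, 4.2), max_depth=3)
        assert t.root.is_leaf and t.root.value == pytest.approx(4.2)

    def test_step_function_split_at_midpoint(self):
        x = np.array([-3.0, -1.0, 2.0, 5.0]).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        t = fit_tree(x, y, max_depth=1, min_leaf=1)
        assert t.root.threshold == pytest.approx(0.5)  # between -1 and 2
        assert np.allclose(t.predict(x), y)

    def test_min_leaf_equal_n_yields_mean_leaf(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        t = fit_tree(X, y, max_depth=3, min_leaf=10)
        assert t.root.is_leaf and t.root.value == pytest.approx(y.mean())

    def test_split_ties_prefer_lowest_feature(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 0.0, 1.0])  # both features split perfectly
        t = fit_tree(x, y, max_depth=1, min_leaf=1)
        assert t.root.feature == 0


class TestBoosting:
    def test_zero_iterations_predicts_training_mean(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        est = BoostedTreesRegressor(n_estimators=0, test_fraction=0.0,
                                    random_state=0).fit(X, y)
        assert np.allclose(est.predict(X), y.mean())

    def test_full_rate_deep_trees_interpolate(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        est = BoostedTreesRegressor(
            n_estimators=200, learning_rate=1.0, test_fraction=0.0,
            subsample=1.0, max_depth=8, min_samples_leaf=1,
            random_state=0).fit(X, y)
        assert est.train_history_[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(est.predict(X), y)

    def test_training_lse_monotone_without_subsampling(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] * 3 + np.sin(X[:, 1]) + rng.normal(scale=0.2, size=60)
        est = BoostedTreesRegressor(
            n_estimators=150, learning_rate=0.1, test_fraction=0.0,
            subsample=1.0, random_state=0).fit(X, y)
        h = est.train_history_
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def test_synthetic_holdout_r2(self):
        # descriptor -> RI map with a linear and a sinusoidal term
        cfg = v.QSRRSimConfig(n_compounds=300, n_informative=2, n_noise=0,
                              coefficients=(95.0, 40.0), ri_intercept=300.0,
                              noise_sd=15.0, ri_band=(-500.0, 1200.0), seed=5)
        X, y, _ = v.make_qsrr_dataset(cfg)
        est = BoostedTreesRegressor(n_estimators=400, learning_rate=0.1,
                                    test_fraction=0.25, subsample=0.8,
                                    random_state=7).fit(X, y)
        te = est.test_indices_
        pred = est.predict(X.iloc[te])
        obs = y.to_numpy()[te]
        r2 = np.corrcoef(obs, pred)[0, 1] ** 2
        assert r2 >= 0.9

    def test_row_permutation_permutes_predictions(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        est = BoostedTreesRegressor(n_estimators=50, test_fraction=0.2,
                                    random_state=1).fit(X, y)
        perm = rng.permutation(40)
        assert np.allclose(est.predict(X[perm]), est.predict(X)[perm])

    def test_feature_column_order_irrelevant_with_names(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X["a"] * 2 + rng.normal(size=50)
        est = BoostedTreesRegressor(n_estimators=60, test_fraction=0.2,
                                    random_state=2).fit(X, y)
        assert np.allclose(est.predict(X[["c", "b", "a"]]), est.predict(X))

    def test_missing_feature_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        est = BoostedTreesRegressor(n_estimators=20, test_fraction=0.2,
                                    random_state=0).fit(X, X["a"])
        with pytest.raises(ValueError, match="missing features"):
            est.predict(X[["a"]].rename(columns={"a": "zzz"}))

    def test_empty_partition_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="empty"):
            BoostedTreesRegressor(test_fraction=0.01,
                                  random_state=0).fit(X, np.ones(3))

    def test_history_matches_kept_trees(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + rng.normal(scale=0.1, size=80)
        est = BoostedTreesRegressor(n_estimators=300, patience=20,
                                    test_fraction=0.25,
                                    random_state=3).fit(X, y)
        assert len(est.trees_) == est.n_iter_ == len(est.train_history_)

    def test_serialization_roundtrip(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X["a"] - X["b"]
        est = BoostedTreesRegressor(n_estimators=30, test_fraction=0.2,
                                    random_state=0).fit(X, y)
        clone = BoostedTreesRegressor.from_dict(est.to_dict())
        assert np.allclose(clone.predict(X), est.predict(X))


class TestGridSearch:
    def test_singleton_grid(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=40)
        cfg = v.BRTConfig(n_trees=100, learning_rate=0.05, seed=1)
        model, res = v.grid_search(X, y, [cfg])
        assert len(res) == 1 and model.n_iter_ >= 1

    def test_dominating_config_wins(self, rng):
        X = rng.normal(size=(120, 3))
        y = 10 * X[:, 0] + 5 * np.sin(2 * X[:, 1]) + rng.normal(scale=0.3,
                                                                size=120)
        weak = v.BRTConfig(n_trees=100, learning_rate=0.0005, subsample=0.5)
        strong = v.BRTConfig(n_trees=500, learning_rate=0.1, subsample=0.8)
        model, res = v.grid_search(X, y, [weak, strong], seed=5)
        res = res.set_index("learning_rate")
        assert res.loc[0.1, "test_lse"] < res.loc[0.0005, "test_lse"]
        assert model.learning_rate == 0.1

    def test_out_of_range_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="outside allowed range"):
            v.grid_search(X, X[:, 0], [v.BRTConfig(n_trees=5)])

    def test_same_seed_reproducible(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(scale=0.2, size=60)
        grid = [v.BRTConfig(n_trees=100, learning_rate=lr)
                for lr in (0.02, 0.1)]
        m1, r1 = v.grid_search(X, y, grid, seed=9)
        m2, r2 = v.grid_search(X, y, grid, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        assert np.allclose(m1.predict(X), m2.predict(X))


class TestImportance:
    def test_single_feature_importance_one(self, rng):
        X = rng.normal(size=(50, 1))
        y = X[:, 0] * 2 + rng.normal(scale=0.1, size=50)
        est = BoostedTreesRegressor(n_estimators=50, test_fraction=0.2,
                                    random_state=0).fit(X, y)
        imp = v.predictor_importance(est)
        assert imp.iloc[0] == pytest.approx(1.0)

    def test_unused_feature_zero(self, rng):
        X = pd.DataFrame({"signal": rng.normal(size=80),
                          "flat": np.zeros(80)})
        y = 3 * X["signal"] + rng.normal(scale=0.1, size=80)
        est = BoostedTreesRegressor(n_estimators=60, test_fraction=0.2,
                                    random_state=1).fit(X, y)
        imp = v.predictor_importance(est)
        assert imp["flat"] == 0.0

    def test_dominant_feature_ranks_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 4)),
                         columns=["big", "small", "n1", "n2"])
        y = 50 * X["big"] + 2 * X["small"] + rng.normal(size=150)
        est = BoostedTreesRegressor(n_estimators=150, test_fraction=0.2,
                                    random_state=2).fit(X, y)
        assert v.predictor_importance(est).index[0] == "big"


class TestLibraryCrossCheck:
    def test_agrees_with_sklearn_gradient_boosting(self):
        """Same data, same role: our learner and scikit-learn's gradient
        boosting should reach comparable holdout accuracy."""
        from sklearn.ensemble import GradientBoostingRegressor

        cfg = v.QSRRSimConfig(n_compounds=250, n_informative=3, n_noise=2,
                              seed=21)
        X, y, _ = v.make_qsrr_dataset(cfg)
        Xa, ya = X.to_numpy(), y.to_numpy()
        tr, te = np.arange(0, 200), np.arange(200, 250)
        ours = BoostedTreesRegressor(
            n_estimators=300, learning_rate=0.1, test_fraction=0.2,
            subsample=1.0, max_depth=3, random_state=0).fit(Xa[tr], ya[tr])
        ref = GradientBoostingRegressor(
            n_estimators=300, learning_rate=0.1, max_depth=3,
            random_state=0).fit(Xa[tr], ya[tr])
        r2_ours = np.corrcoef(ya[te], ours.predict(Xa[te]))[0, 1] ** 2
        r2_ref = np.corrcoef(ya[te], ref.predict(Xa[te]))[0, 1] ** 2
        assert r2_ours == pytest.approx(r2_ref, abs=0.1)
        assert r2_ours > 0.6
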