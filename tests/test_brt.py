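"""Boosted-regression-tree correctness against hand-checkable oracles."""

import numpy as np
import pytest
from scipy.special import expit, logit

from vectorsdm.brt import BRTConfig, BRTModel, fit_brt, predict_brt, variable_importance


def exhaustive_stump_oracle(x, r, w, hess_w):
    """Brute-force best single split of 1-D data by weighted SSE reduction.

    Returns (threshold, left_value, right_value) with leaf values given by
    the Bernoulli Newton step. Independent of the tree grower: enumerates
    every midpoint split directly.
    """
    best = None
    xs = np.sort(np.unique(x))
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = (lo + hi) / 2
        left, right = x <= thr, x > thr
        sse_parent = ((w * r**2).sum() - (w * r).sum() ** 2 / w.sum())
        sse_children = sum(
            (w[m] * r[m] ** 2).sum() - (w[m] * r[m]).sum() ** 2 / w[m].sum()
            for m in (left, right)
        )
        gain = sse_parent - sse_children
        if best is None or gain > best[0]:
            lv = (w[left] * r[left]).sum() / (hess_w[left]).sum()
            rv = (w[right] * r[right]).sum() / (hess_w[right]).sum()
            best = (gain, thr, lv, rv)
    return best[1], best[2], best[3]


class TestSingleStump:
    def test_stump_matches_exhaustive_split_search(self):
        # 6-point 1-D toy: labels mostly separate around x ~ 3.5
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        w = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 1.0])
        cfg = BRTConfig(n_trees=1, shrinkage=1.0, tree_complexity=2,
                        bag_fraction=1.0, min_obs_leaf=1, seed=0)
        model = fit_brt(x[:, None], y, w, cfg)
        F0 = model.intercept
        p0 = expit(F0)
        r = y - p0
        hess = w * p0 * (1 - p0)
        thr, lv, rv = exhaustive_stump_oracle(x, r, w, hess)
        tree = model.trees[0]
        assert tree["threshold"] == pytest.approx(thr)
        assert tree["left"]["value"] == pytest.approx(lv)
        assert tree["right"]["value"] == pytest.approx(rv)

    def test_intercept_is_weighted_prevalence_logit(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = fit_brt(np.zeros((4, 1)), y, None,
                    BRTConfig(n_trees=1, bag_fraction=1.0, min_obs_leaf=1))
        assert m.intercept == pytest.approx(0.0)  # logit(0.5)
        w = np.array([3.0, 1.0, 1.0, 1.0])
        m2 = fit_brt(np.arange(4)[:, None].astype(float), y, w,
                     BRTConfig(n_trees=1, bag_fraction=1.0, min_obs_leaf=1))
        assert m2.intercept == pytest.approx(logit(2 / 6))


class TestPrediction:
    def test_zero_tree_model_predicts_constant_prevalence(self):
        model = BRTModel(intercept=logit(0.3), trees=[], shrinkage=0.1,
                         band_names=["a", "b"], config=BRTConfig())
        p = predict_brt(model, np.random.default_rng(0).normal(size=(10, 2)))
        assert np.allclose(p, 0.3)

    def test_duplicate_rows_identical_predictions(self, rng):
        X = rng.normal(size=(50, 3))
        y = (rng.uniform(size=50) < expit(X[:, 0])).astype(float)
        y[:2] = [0, 1]
        m = fit_brt(X, y, None, BRTConfig(n_trees=20, shrinkage=0.1, seed=2))
        Xdup = np.vstack([X[5], X[5]])
        p = predict_brt(m, Xdup)
        assert p[0] == p[1]

    def test_predictions_match_manual_tree_traversal(self, rng):
        X = rng.normal(size=(60, 4))
        y = (rng.uniform(size=60) < expit(1.5 * X[:, 1])).astype(float)
        y[:2] = [0, 1]
        m = fit_brt(X, y, None, BRTConfig(n_trees=15, shrinkage=0.2, seed=5))
        Xq = rng.normal(size=(20, 4))

        def traverse(node, row):
            while "value" not in node:
                node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
            return node["value"]

        manual = np.array([
            expit(m.intercept + m.shrinkage * sum(traverse(t, row) for t in m.trees))
            for row in Xq
        ])
        assert np.allclose(predict_brt(m, Xq), manual)

    def test_band_count_mismatch_rejected(self):
        model = BRTModel(intercept=0.0, trees=[], shrinkage=0.1,
                         band_names=["a"], config=BRTConfig())
        with pytest.raises(ValueError):
            predict_brt(model, np.zeros((3, 2)))


class TestWeightSemantics:
    @pytest.fixture
    def toy(self, rng):
        X = rng.normal(size=(80, 3))
        y = (rng.uniform(size=80) < expit(2 * X[:, 0] - X[:, 2])).astype(float)
        y[:2] = [0, 1]
        w = rng.uniform(0.5, 2.5, size=80)
        return X, y, w

    def test_doubling_all_weights_leaves_model_unchanged(self, toy):
        X, y, w = toy
        cfg = BRTConfig(n_trees=25, shrinkage=0.1, seed=3)
        m1 = fit_brt(X, y, w, cfg)
        m2 = fit_brt(X, y, 2 * w, cfg)
        assert np.allclose(predict_brt(m1, X), predict_brt(m2, X))
        assert m1.intercept == pytest.approx(m2.intercept)

    def test_weight_two_equals_duplicated_record_at_full_bag(self, toy):
        X, y, _ = toy
        w = np.ones(len(y))
        w[7] = 2.0
        cfg = BRTConfig(n_trees=15, shrinkage=0.1, bag_fraction=1.0,
                        min_obs_leaf=1, seed=4)
        m_weighted = fit_brt(X, y, w, cfg)
        X_dup = np.vstack([X, X[7]])
        y_dup = np.append(y, y[7])
        m_dup = fit_brt(X_dup, y_dup, np.ones(len(y_dup)), cfg)
        assert np.allclose(predict_brt(m_weighted, X), predict_brt(m_dup, X))


class TestDevianceAndConvergence:
    def test_training_deviance_non_increasing_at_full_bag(self, rng):
        X = rng.normal(size=(100, 3))
        y = (rng.uniform(size=100) < expit(X[:, 0])).astype(float)
        y[:2] = [0, 1]
        m = fit_brt(X, y, None, BRTConfig(n_trees=60, shrinkage=0.1,
                                          bag_fraction=1.0, seed=6))
        dev = np.array(m.train_deviance)
        assert (np.diff(dev) <= 1e-12).all()

    def test_separable_toy_training_auc_approaches_one(self):
        from vectorsdm.validation import compute_auc

        x = np.linspace(0, 1, 40)
        y = (x > 0.5).astype(float)
        m = fit_brt(x[:, None], y, None,
                    BRTConfig(n_trees=300, shrinkage=0.05, bag_fraction=1.0,
                              min_obs_leaf=1, seed=7))
        p = predict_brt(m, x[:, None])
        assert compute_auc(p[y == 1], p[y == 0]) == 1.0

    def test_early_stopping_trims_tree_list(self, rng):
        X = rng.normal(size=(200, 2))
        y = (rng.uniform(size=200) < expit(3 * X[:, 0])).astype(float)
        y[:2] = [0, 1]
        cfg = BRTConfig(n_trees=400, shrinkage=0.3, bag_fraction=1.0, seed=8,
                        early_stopping=True, patience=20)
        m = fit_brt(X, y, None, cfg)
        assert m.n_trees < 400
        assert len(m.holdout_deviance) == m.n_trees


class TestVariableImportance:
    def test_single_stump_gives_full_influence_to_split_band(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        X = np.column_stack([x, np.zeros(6)])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        m = fit_brt(X, y, None, BRTConfig(n_trees=1, shrinkage=1.0, bag_fraction=1.0,
                                          min_obs_leaf=1), band_names=["signal", "noise"])
        imp = variable_importance(m)
        assert imp["signal"] == pytest.approx(100.0)
        assert imp["noise"] == pytest.approx(0.0)

    def test_influences_sum_to_100(self, rng):
        X = rng.normal(size=(80, 5))
        y = (rng.uniform(size=80) < expit(X[:, 3])).astype(float)
        y[:2] = [0, 1]
        m = fit_brt(X, y, None, BRTConfig(n_trees=30, shrinkage=0.1, seed=9))
        assert sum(variable_importance(m).values()) == pytest.approx(100.0, abs=1e-9)

    def test_active_bands_recovered_in_nine_of_ten_seeds(self):
        # 6 covariates, 2 truly active: the two active bands should top the
        # relative-influence ranking in nearly every seeded fit
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(400, 6))
            eta = 2.5 * X[:, 1] - 2.5 * X[:, 4]
            y = (rng.uniform(size=400) < expit(eta)).astype(float)
            if len(np.unique(y)) < 2:
                continue
            m = fit_brt(X, y, None, BRTConfig(n_trees=100, shrinkage=0.1, seed=seed))
            top2 = sorted(variable_importance(m), key=variable_importance(m).get)[-2:]
            if set(top2) == {"band_1", "band_4"}:
                hits += 1
        assert hits >= 9

    def test_zero_tree_model_rejected(self):
        model = BRTModel(intercept=0.0, trees=[], shrinkage=0.1,
                         band_names=["a"], config=BRTConfig())
        with pytest.raises(ValueError):
            variable_importance(model)


class TestValidationAndSerialisation:
    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_brt(np.zeros((5, 1)), np.ones(5), None, BRTConfig(n_trees=1))

    def test_non_finite_covariates_rejected(self):
        X = np.zeros((4, 1))
        X[0] = np.nan
        with pytest.raises(ValueError):
            fit_brt(X, np.array([0, 1, 0, 1.0]), None, BRTConfig(n_trees=1))

    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.uniform(size=60) < expit(X[:, 0])).astype(float)
        y[:2] = [0, 1]
        m = fit_brt(X, y, None, BRTConfig(n_trees=10, shrinkage=0.1, seed=1))
        m2 = BRTModel.from_json(m.to_json())
        assert np.array_equal(predict_brt(m, X), predict_brt(m2, X))
        assert m2.config == m.config

    def test_same_seed_same_model(self, rng):
        X = rng.normal(size=(70, 3))
        y = (rng.uniform(size=70) < expit(X[:, 1])).astype(float)
        y[:2] = [0, 1]
        cfg = BRTConfig(n_trees=12, shrinkage=0.1, seed=21)
        assert fit_brt(X, y, None, cfg).to_json() == fit_brt(X, y, None, cfg).to_json()
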