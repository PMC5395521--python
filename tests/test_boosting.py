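import numpy as np
import pandas as pd
import pytest

from simboost import (QuantileBoostRegressor, SimBoostQuantRegressor,
                      SimBoostRegressor, quantile_loss)
from simboost.boosting import predict_interval
from simboost.errors import ConfigError


def _finite_difference_grad(y, u, alpha, weighted, eps=1e-6):
    lo, _ = quantile_loss(y, u - eps, alpha, weighted)
    hi, _ = quantile_loss(y, u + eps, alpha, weighted)
    return (hi - lo) / (2 * eps)


class TestQuantileLoss:
    def test_zero_at_equality(self):
        loss, grad = quantile_loss(2.0, 2.0, 0.3)
        assert loss == 0.0 and grad == 0.0

    def test_weighted_gradient_magnitude(self):
        _, grad = quantile_loss(2.0, 1.0, 0.9, weighted=True)
        assert abs(grad) == pytest.approx(1.8)

    def test_median_loss_is_half_absolute_error(self):
        y = np.array([3.0, -1.0, 0.5])
        u = np.array([1.0, 2.0, 0.5])
        loss, _ = quantile_loss(y, u, 0.5)
        np.testing.assert_allclose(loss, 0.5 * np.abs(y - u))

    @pytest.mark.parametrize("weighted", [False, True])
    def test_gradient_matches_finite_differences(self, weighted):
        rng = np.random.default_rng(42)
        y = rng.uniform(0.1, 10.0, size=1000)
        u = rng.uniform(0.1, 10.0, size=1000)
        # keep points away from the kink where the derivative jumps
        u = np.where(np.abs(y - u) < 1e-4, u + 0.01, u)
        alpha = rng.uniform(0.01, 0.99, size=1000)
        for i in range(1000):
            _, grad = quantile_loss(y[i], u[i], alpha[i], weighted)
            fd = _finite_difference_grad(y[i], u[i], alpha[i], weighted)
            assert abs(grad - fd) < 1e-6

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigError):
            quantile_loss(1.0, 0.0, 1.5)


@pytest.fixture
def separable_toy():
    rng = np.random.default_rng(1)
    x = rng.uniform(-1, 1, size=(200, 1))
    y = (x[:, 0] > 0).astype(float)
    return pd.DataFrame(x, columns=["f0"]), y


class TestSimBoostRegressor:
    def test_constant_labels_are_reproduced(self):
        X = pd.DataFrame({"f": np.arange(50.0)})
        y = np.full(50, 3.7)
        reg = SimBoostRegressor(n_rounds=20, seed=0).fit(X, y)
        np.testing.assert_allclose(reg.predict(X), 3.7, atol=1e-6)

    def test_single_stump_leaves_equal_per_leaf_means(self, separable_toy):
        X, y = separable_toy
        reg = SimBoostRegressor(n_rounds=1, max_depth=1, learning_rate=1.0,
                                gamma=0.0, reg_lambda=0.0, base_score=0.0,
                                subsample=1.0, colsample_bytree=1.0,
                                seed=0).fit(X, y)
        pred = reg.predict(X)
        # closed form: leaf weight -sum(g)/(sum(h)+lambda) = mean residual
        np.testing.assert_allclose(pred[X["f0"] > 0], y[X["f0"] > 0].mean(), atol=1e-6)
        np.testing.assert_allclose(pred[X["f0"] <= 0], y[X["f0"] <= 0].mean(), atol=1e-6)

    def test_training_rmse_non_increasing(self, separable_toy):
        X, y = separable_toy
        reg = SimBoostRegressor(n_rounds=50, subsample=1.0, colsample_bytree=1.0,
                                seed=0).fit(X, y + np.arange(len(y)) * 0.01)
        assert np.all(np.diff(reg.train_rmse_history_) <= 1e-9)

    def test_non_finite_labels_rejected(self, separable_toy):
        X, y = separable_toy
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ConfigError):
            SimBoostRegressor().fit(X, y)

    def test_deterministic_under_fixed_seed(self, separable_toy):
        X, y = separable_toy
        p1 = SimBoostRegressor(n_rounds=30, seed=3).fit(X, y).predict(X)
        p2 = SimBoostRegressor(n_rounds=30, seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestFeatureImportance:
    def test_predictive_feature_outranks_noise(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"signal": rng.normal(size=300),
                          "noise": rng.normal(size=300)})
        y = X["signal"].to_numpy()
        reg = SimBoostRegressor(n_rounds=50, subsample=1.0,
                                colsample_bytree=1.0, seed=0).fit(X, y)
        imp = dict(reg.feature_importance())
        assert imp["signal"] > imp["noise"]
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert reg.feature_importance()[0][0] == "signal"

    def test_single_feature_has_importance_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"only": rng.normal(size=100)})
        reg = SimBoostRegressor(n_rounds=10, seed=0).fit(X, X["only"].to_numpy())
        assert reg.feature_importance()[0] == ("only", pytest.approx(1.0))


class TestQuantilePair:
    def test_constant_labels_give_degenerate_interval(self):
        X = pd.DataFrame({"f": np.arange(100.0)})
        y = np.full(100, 2.0)
        q = SimBoostQuantRegressor(alpha=0.1, n_rounds=50, seed=0).fit(X, y)
        iv = q.predict_interval(X)
        np.testing.assert_allclose(iv["midpoint"], 2.0, atol=0.05)
        assert iv["width"].max() < 0.1

    def test_uninformative_features_recover_marginal_quantiles(self):
        rng = np.random.default_rng(0)
        n = 3000
        X = pd.DataFrame({"f": np.zeros(n)})
        y = rng.uniform(0, 1, size=n)
        lo = QuantileBoostRegressor(alpha=0.1, weighted=False, n_rounds=300,
                                    max_depth=2, subsample=1.0,
                                    seed=0).fit(X, y)
        hi = QuantileBoostRegressor(alpha=0.9, weighted=False, n_rounds=300,
                                    max_depth=2, subsample=1.0,
                                    seed=0).fit(X, y)
        assert np.mean(lo.predict(X)) == pytest.approx(0.1, abs=0.05)
        assert np.mean(hi.predict(X)) == pytest.approx(0.9, abs=0.05)

    def test_swapping_alpha_swaps_model_roles(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.normal(size=200)})
        y = rng.normal(size=200) + 5.0
        pair = SimBoostQuantRegressor(alpha=0.2, n_rounds=30, seed=7).fit(X, y)
        solo_high = QuantileBoostRegressor(alpha=0.8, weighted=True, n_rounds=30,
                                           seed=7).fit(X, y)
        np.testing.assert_array_equal(pair.model_high_.predict(X),
                                      solo_high.predict(X))

    def test_interval_invariants_and_midpoint(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"f": rng.normal(size=400)})
        y = 6.0 + X["f"].to_numpy() + rng.normal(0, 0.5, size=400)
        q = SimBoostQuantRegressor(alpha=0.1, n_rounds=100, seed=0).fit(X, y)
        iv = q.predict_interval(X)
        assert (iv["lower"] <= iv["upper"]).all()
        np.testing.assert_allclose(iv["midpoint"],
                                   (iv["lower"] + iv["upper"]) / 2.0)
        np.testing.assert_allclose(iv["width"], iv["upper"] - iv["lower"])
        np.testing.assert_array_equal(q.predict(X), iv["midpoint"].to_numpy())
        assert 0.0 <= q.crossing_rate_ <= 1.0

    def test_crossing_repair_orders_the_interval(self):
        # two deliberately mis-ordered models: "low" trained on high labels
        X = pd.DataFrame({"f": np.zeros(50)})
        hi_labels = np.full(50, 5.0)
        lo_labels = np.full(50, 3.0)
        model_low = QuantileBoostRegressor(alpha=0.1, weighted=False,
                                           n_rounds=50, seed=0).fit(X, hi_labels)
        model_high = QuantileBoostRegressor(alpha=0.9, weighted=False,
                                            n_rounds=50, seed=0).fit(X, lo_labels)
        iv = predict_interval(model_low, model_high, X)
        assert (iv["lower"] <= iv["upper"]).all()
        assert iv["lower"].iloc[0] == pytest.approx(3.0, abs=0.1)
        assert iv["upper"].iloc[0] == pytest.approx(5.0, abs=0.1)
        assert iv["midpoint"].iloc[0] == pytest.approx(4.0, abs=0.1)

    def test_alpha_must_define_a_proper_interval(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(ConfigError):
            SimBoostQuantRegressor(alpha=0.7).fit(X, np.arange(10.0))

    def test_weighted_loss_requires_nonnegative_labels(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(ConfigError):
            QuantileBoostRegressor(alpha=0.1, weighted=True).fit(
                X, np.arange(10.0) - 5.0)
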