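"""Regression trees, boosting, and the spectral feature extractor."""

import itertools

import numpy as np
import pytest

from bispkpd.exceptions import ValidationError
from bispkpd.gbdt import (
    BoostedEnsemble,
    eeg_features,
    fit_boosted,
    fit_tree,
    predict,
)


def exhaustive_stump_sse(X, y):
    """Brute-force oracle: best SSE over every (feature, midpoint) stump."""
    n, d = X.shape
    best = float(np.sum((y - y.mean()) ** 2))
    for j in range(d):
        for thr in np.unique(X[:, j]):
            mask = X[:, j] <= thr
            if mask.all() or not mask.any():
                continue
            sse = np.sum((y[mask] - y[mask].mean()) ** 2) + np.sum(
                (y[~mask] - y[~mask].mean()) ** 2
            )
            best = min(best, float(sse))
    return best


class TestRegressionTree:
    def test_constant_residuals_yield_single_leaf(self):
        X = np.arange(6.0)[:, None]
        tree = fit_tree(X, np.full(6, 2.5), max_depth=4)
        assert tree.depth() == 0
        assert np.allclose(tree.predict(X), 2.5)

    def test_two_point_split_is_exact(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 10.0])
        tree = fit_tree(X, y, max_depth=1)
        assert tree.root.threshold == pytest.approx(0.5)
        assert np.allclose(tree.predict(X), y)

    def test_xor_fits_at_depth_two(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 1.0, 0.0])
        tree = fit_tree(X, y, max_depth=2)
        assert np.mean((tree.predict(X) - y) ** 2) == pytest.approx(0.0, abs=1e-24)

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_stump_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        X = rng.integers(0, 5, size=(n, 3)).astype(float)
        y = rng.normal(size=n)
        tree = fit_tree(X, y, max_depth=1)
        pred = tree.predict(X)
        assert float(np.sum((y - pred) ** 2)) == pytest.approx(
            exhaustive_stump_sse(X, y), abs=1e-9
        )

    def test_depth_budget_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        tree = fit_tree(X, rng.normal(size=40), max_depth=3)
        assert tree.depth() <= 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_tree(np.empty((0, 1)), np.empty(0))

    def test_deterministic_tie_break_prefers_lowest_feature(self):
        # identical columns: the split must land on feature 0
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0.0, 0.0, 5.0, 5.0])
        tree = fit_tree(X, y, max_depth=1)
        assert tree.root.feature == 0
        assert tree.root.threshold == pytest.approx(1.5)


class TestBoosting:
    def test_constant_target_fits_in_one_stage(self):
        X = np.arange(5.0)[:, None]
        ens = fit_boosted(X, np.full(5, 4.2), n_stages=1, shrinkage=1.0)
        assert np.allclose(ens.predict(X), 4.2)

    def test_single_stage_equals_single_tree(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        ens = fit_boosted(X, y, n_stages=1, shrinkage=1.0, max_depth=3)
        tree = fit_tree(X, y, max_depth=3)
        assert np.allclose(ens.predict(X), tree.predict(X))

    def test_step_function_converges(self):
        x = np.linspace(0, 1, 50)
        y = (x > 0.5).astype(float)
        ens = fit_boosted(x[:, None], y, n_stages=200, shrinkage=0.1, max_depth=1)
        assert ens.train_mse[-1] < 1e-3
        assert np.all(np.diff(ens.train_mse) <= 1e-12)

    def test_interpolation_with_unlimited_depth(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 1))
        y = rng.normal(size=20)
        ens = fit_boosted(X, y, n_stages=1, shrinkage=1.0, max_depth=50)
        assert np.mean((ens.predict(X) - y) ** 2) == pytest.approx(0.0, abs=1e-20)

    def test_empty_ensemble_predicts_f0(self):
        ens = BoostedEnsemble(trees=(), shrinkage=0.1, f0=0.0, n_features=2)
        assert np.all(predict(ens, np.ones((4, 2))) == 0.0)

    def test_staged_predict_terminates_at_full_prediction(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        ens = fit_boosted(X, y, n_stages=10, shrinkage=0.5)
        *_, last = ens.staged_predict(X)
        assert np.allclose(last, ens.predict(X))

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        ens = fit_boosted(rng.normal(size=(10, 3)), rng.normal(size=10), n_stages=2)
        with pytest.raises(ValidationError, match="mismatch"):
            ens.predict(np.ones((4, 2)))

    def test_json_round_trip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        ens = fit_boosted(X, y, n_stages=5, shrinkage=0.3)
        clone = BoostedEnsemble.from_dict(ens.to_dict())
        assert np.allclose(clone.predict(X), ens.predict(X))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValidationError):
            fit_boosted(np.ones((3, 1)), np.ones(3), n_stages=0)
        with pytest.raises(ValidationError):
            fit_boosted(np.ones((3, 1)), np.ones(3), shrinkage=0.0)


class TestSpectralFeatures:
    def test_pure_alpha_tone_dominates(self):
        t = np.arange(0, 4, 1 / 128)
        fm = eeg_features(np.sin(2 * np.pi * 10.0 * t), fs=128, epoch_seconds=2.0)
        frac = fm.features["alpha"] / fm.features["total_power"]
        assert np.all(frac > 0.9)

    def test_silent_signal_has_zero_power_and_entropy(self):
        fm = eeg_features(np.zeros(512), fs=128, epoch_seconds=2.0)
        assert np.all(fm.features[["delta", "theta", "alpha", "beta", "gamma"]] == 0.0)
        assert np.all(fm.features["spectral_entropy"] == 0.0)
        assert np.all(fm.features["sef95"] == 0.0)

    def test_white_noise_features_are_reproducible(self):
        rng = np.random.default_rng(12)
        sig = rng.normal(size=1024)
        a = eeg_features(sig, fs=128).features
        b = eeg_features(sig.copy(), fs=128).features
        assert a.equals(b)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            eeg_features(np.ones(10), fs=128, epoch_seconds=2.0)
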