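"""Splits, training with early stopping, prediction, and metrics."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from adscout import synthetic
from adscout.features import encode_sequences
from adscout.regressor import (NormalizationParams, RegressorSpec,
                               TrainingConfig, dedup_labeled,
                               evaluate_metrics, fit_regressor,
                               load_checkpoint, save_checkpoint,
                               spectral_ood_split, stratified_split)


class TestStratifiedSplit:
    def test_partition_is_disjoint_and_exhaustive(self, rng):
        labels = rng.normal(size=200)
        split = stratified_split(labels, seed=3)
        joined = np.concatenate([split.train, split.val, split.test])
        assert len(joined) == 200
        assert len(np.unique(joined)) == 200

    def test_above_median_balance_within_one_count(self, rng):
        labels = rng.normal(size=1000)
        split = stratified_split(labels, seed=7)
        above = labels > np.median(labels)
        for part in (split.train, split.val, split.test):
            assert abs(above[part].mean() - 0.5) <= 1 / len(part)

    def test_same_seed_reproduces_partition_exactly(self, rng):
        labels = rng.normal(size=120)
        a = stratified_split(labels, seed=11)
        b = stratified_split(labels, seed=11)
        assert (a.train == b.train).all()
        assert (a.val == b.val).all()
        assert (a.test == b.test).all()

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.arange(9.0))

    def test_dedup_labeled_keeps_first(self):
        import pandas as pd

        frame = pd.DataFrame({"sequence": ["AA", "AA", "CC"],
                              "activity": [1.0, 2.0, 3.0]})
        out = dedup_labeled(frame)
        assert list(out["activity"]) == [1.0, 3.0]


class TestSpectralOODSplit:
    def test_recovers_composition_regimes(self):
        lib = synthetic.sample_library(
            60, mix={"acidic": 0.5, "basic": 0.5}, seed=5)
        x = encode_sequences(lib["sequence"])
        train_idx, test_idx, clusters = spectral_ood_split(x, n_clusters=2,
                                                          seed=0)
        truth = (lib["regime"] == "acidic").astype(int)
        assert adjusted_rand_score(truth, clusters) >= 0.9
        assert len(train_idx) + len(test_idx) == 60
        assert not set(train_idx) & set(test_idx)

    def test_permutation_invariance_up_to_relabeling(self):
        lib = synthetic.sample_library(
            40, mix={"acidic": 0.5, "basic": 0.5}, seed=6)
        x = encode_sequences(lib["sequence"])
        _, _, clusters = spectral_ood_split(x, 2, seed=0)
        perm = np.random.default_rng(1).permutation(40)
        _, _, permuted = spectral_ood_split(x[perm], 2, seed=0)
        assert adjusted_rand_score(clusters[perm], permuted) == 1.0

    def test_singleton_clusters(self):
        lib = synthetic.sample_library(8, mix={"background": 1.0}, seed=0)
        x = encode_sequences(lib["sequence"])
        train_idx, test_idx, _ = spectral_ood_split(x, n_clusters=8, seed=0)
        assert len(test_idx) == 1

    def test_degenerate_similarity_raises(self):
        x = np.ones((10, 5, 20))
        with pytest.raises(ValueError, match="degenerate"):
            spectral_ood_split(x, 2)


class TestNormalization:
    def test_z_inverse_is_identity(self, rng):
        norm = NormalizationParams(2.0, 1.7)
        y = rng.normal(size=50)
        assert np.allclose(norm.inverse(norm.z(y)), y, atol=1e-9)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationParams(1.0, 0.0)


@pytest.fixture(scope="module")
def linear_fit():
    """A compact net trained on a noise-free linear composition target."""
    lib = synthetic.sample_library(400, mix={"background": 1.0}, seed=8)
    x = encode_sequences(lib["sequence"])
    y = np.array([2.0 * s.count("W") - 1.0 * s.count("K")
                  for s in lib["sequence"]], dtype=float)
    split = stratified_split(y, seed=8)
    model = fit_regressor(x, y, split.train, split.val,
                          TrainingConfig(seed=8, max_epochs=60),
                          RegressorSpec.compact())
    return x, y, split, model


class TestFitRegressor:
    def test_recovers_noise_free_linear_target(self, linear_fit):
        x, y, split, model = linear_fit
        metrics = evaluate_metrics(model.predict(x[split.test]),
                                   y[split.test])
        assert metrics.pearson_r >= 0.95

    def test_early_stopping_keeps_best_epoch(self, linear_fit):
        _, _, _, model = linear_fit
        val = [h["val_loss"] for h in model.history]
        best = int(np.argmin(val))
        # either the patience rule fired exactly, or max_epochs was hit
        assert (len(val) == best + model.config.patience + 1
                or len(val) == model.config.max_epochs)

    def test_batch_prediction_equals_per_tile(self, linear_fit):
        x, _, split, model = linear_fit
        sub = x[split.test[:7]]
        batched = model.predict(sub)
        single = np.concatenate([model.predict(sub[i:i + 1])
                                 for i in range(7)])
        assert np.allclose(batched, single, atol=1e-12)

    def test_same_seed_same_model(self, linear_fit):
        x, y, split, model = linear_fit
        rerun = fit_regressor(x, y, split.train, split.val,
                              TrainingConfig(seed=8, max_epochs=60),
                              RegressorSpec.compact())
        assert rerun.history == model.history
        assert np.allclose(rerun.predict(x[:5]), model.predict(x[:5]),
                           atol=1e-12)

    def test_constant_labels_rejected(self, rng):
        x = rng.normal(size=(20, 10, 20))
        y = np.full(20, 3.0)
        with pytest.raises(ValueError, match="variance"):
            fit_regressor(x, y, np.arange(15), np.arange(15, 20))

    def test_checkpoint_round_trip(self, linear_fit, tmp_path):
        x, _, _, model = linear_fit
        save_checkpoint(model, tmp_path / "ckpt")
        restored = load_checkpoint(tmp_path / "ckpt")
        assert np.allclose(restored.predict(x[:9]), model.predict(x[:9]),
                           atol=1e-12)

    def test_beats_mean_predictor_baseline(self, linear_fit):
        x, y, split, model = linear_fit
        preds = model.predict(x[split.val])
        baseline = float(((y[split.val] - y[split.train].mean()) ** 2).mean())
        assert float(((preds - y[split.val]) ** 2).mean()) <= baseline


class TestMetrics:
    def test_perfect_predictions(self):
        m = evaluate_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0
        assert m.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert m.spearman_rho == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated(self):
        y = np.array([-1.0, 0.0, 1.0])
        assert evaluate_metrics(-y, y).pearson_r == pytest.approx(-1.0)

    def test_hand_computed_toy_vectors(self):
        m = evaluate_metrics([1.5, 1.5, 3.5, 3.5], [1.0, 2.0, 3.0, 4.0])
        assert m.rmse == pytest.approx(0.5)
        assert m.pearson_r == pytest.approx(2 / np.sqrt(5), abs=1e-9)

    def test_nan_pairs_dropped_and_counted(self):
        m = evaluate_metrics([1.0, 2.0, 3.0], [1.0, np.nan, 3.0])
        assert m.n == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics([1.0], [1.0])
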