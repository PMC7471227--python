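"""The multi-input CNN: dimensional bookkeeping, training, prediction."""

import numpy as np
import pytest

from mitopo.model import (ModelConfig, build_model, grid_search, predict,
                          predict_proba, train)
from mitopo.topomap import head_grid


def blobs(n=60, n_bands=1, shape=(42, 56), seed=0, noise=0.1):
    """Two linearly separable classes: a square blob on the left or right."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise, (n, n_bands) + shape)
    y = np.arange(n) % 2
    for k in range(n):
        r, c = (12, 15) if y[k] == 0 else (12, 40)
        x[k, :, r - 3:r + 3, c - 3:c + 3] += 1.0
    return x, y


class TestArchitecture:
    def test_four_band_branch_flatten(self):
        cfg = ModelConfig(n_bands=4, band_mode="branches")
        assert cfg.pooled_shape == (21, 28)
        assert cfg.flatten_dim == 21 * 28 * 2 * 4

    def test_channel_mode_flatten_is_1176(self):
        # the printed layer-table sizing: 2 feature maps regardless of bands
        cfg = ModelConfig(n_bands=4, band_mode="channels")
        assert cfg.pooled_shape == (21, 28)
        assert cfg.flatten_dim == 1176

    def test_three_class_output_width(self):
        cfg = ModelConfig(n_classes=3, hidden_units=10)
        model = build_model(cfg)
        assert model.net.params["w2"].shape[1] == 3

    def test_odd_image_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(image_shape=(41, 56))

    def test_dense_weight_matrix_shape(self):
        cfg = ModelConfig(n_bands=2, hidden_units=30)
        model = build_model(cfg)
        assert model.dense_weights.shape == (cfg.flatten_dim, 30)


class TestTraining:
    CFG = dict(n_bands=1, hidden_units=20, epochs=50, patience=0,
               batch_size=16, n_classes=2)

    def test_learns_separable_blobs(self):
        x, y = blobs()
        cfg = ModelConfig(seed=1, **self.CFG)
        model = train(build_model(cfg), x, y, cfg)
        acc = (predict_proba(model, x).argmax(1) == y).mean()
        assert acc >= 0.95

    def test_shuffled_labels_stay_near_chance(self):
        x, y = blobs(n=40)
        rng = np.random.default_rng(9)
        y_shuf = rng.permutation(y)
        x_test, y_test = blobs(n=40, seed=5)
        y_test = rng.permutation(y_test)
        cfg = ModelConfig(seed=2, **{**self.CFG, "epochs": 30})
        model = train(build_model(cfg), x, y_shuf, cfg)
        acc = (predict_proba(model, x_test).argmax(1) == y_test).mean()
        assert abs(acc - 0.5) <= 0.15

    def test_same_seed_identical_training(self):
        x, y = blobs(n=30)
        cfg = ModelConfig(seed=3, **{**self.CFG, "epochs": 10})
        m1 = train(build_model(cfg), x, y, cfg)
        m2 = train(build_model(cfg), x, y, cfg)
        assert m1.history["loss"][-1] == pytest.approx(
            m2.history["loss"][-1], abs=1e-12)

    def test_zero_penalty_reduces_to_no_regularizer(self):
        cfg = ModelConfig(l1=0.0, l2=0.0, **{k: v for k, v in self.CFG.items()
                                             if k not in ("l1", "l2")})
        model = build_model(cfg)
        assert model.net.penalty() == 0.0

    def test_early_stopping_restores_best_weights(self):
        x, y = blobs(n=40)
        cfg = ModelConfig(seed=4, n_bands=1, hidden_units=20, epochs=200,
                          patience=3, batch_size=16, n_classes=2)
        model = train(build_model(cfg), x, y, cfg)
        assert len(model.history["loss"]) < 200


class TestPrediction:
    def _trained(self):
        x, y = blobs(n=30)
        cfg = ModelConfig(seed=5, n_bands=1, hidden_units=20, epochs=30,
                          patience=0, batch_size=16, n_classes=2)
        return train(build_model(cfg), x, y, cfg), x, y

    def test_probabilities_sum_to_one(self):
        model, x, _ = self._trained()
        probs = predict_proba(model, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0.0)

    def test_duplicated_input_identical_prediction(self):
        model, x, _ = self._trained()
        pair = np.stack([x[0], x[0]])
        preds = predict(model, pair)
        np.testing.assert_array_equal(preds[0].probabilities,
                                      preds[1].probabilities)
        assert preds[0].predicted == preds[1].predicted

    def test_predictions_match_planted_labels(self):
        model, x, y = self._trained()
        acc = np.mean([p.predicted for p in predict(model, x)] == y)
        assert acc >= 0.95

    def test_shape_mismatch_rejected(self):
        model, _, _ = self._trained()
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 3, 42, 56)))


class TestInputMask:
    def test_off_mask_perturbation_cannot_move_predictions(self):
        _, _, mask = head_grid((42, 56))
        x, y = blobs(n=30)
        x *= mask
        cfg = ModelConfig(seed=6, n_bands=1, hidden_units=20, epochs=30,
                          patience=0, batch_size=16, n_classes=2)
        model = train(build_model(cfg, input_mask=mask), x, y, cfg)
        base = predict_proba(model, x[:5])
        off = np.argwhere(~mask)[0]
        on = (12, 28)
        assert mask[on]
        x_off = x[:5].copy()
        x_off[:, :, off[0], off[1]] += 5.0
        x_on = x[:5].copy()
        x_on[:, :, on[0], on[1]] += 5.0
        d_off = np.abs(predict_proba(model, x_off) - base).max()
        d_on = np.abs(predict_proba(model, x_on) - base).max()
        assert d_off == 0.0
        assert d_on > 0.0


class TestGridSearch:
    def test_degenerate_grid_returns_that_config(self):
        x, y = blobs(n=24)
        best, table = grid_search(x, y, hu_grid=[8], reg_grid=[0.01],
                                  base_cfg=ModelConfig(
                                      n_bands=1, hidden_units=8, epochs=5,
                                      patience=0, n_classes=2, seed=0),
                                  folds=2, repeats=1, seed=0)
        assert best.hidden_units == 8
        assert best.l1 == best.l2 == 0.01
        # one row per config x repeat x fold
        assert len(table) == 1 * 1 * 2

    def test_grid_enumeration_counts(self):
        x, y = blobs(n=24)
        best, table = grid_search(x, y, hu_grid=[4, 8], reg_grid=[0.0, 0.01],
                                  base_cfg=ModelConfig(
                                      n_bands=1, hidden_units=8, epochs=3,
                                      patience=0, n_classes=2, seed=0),
                                  folds=2, repeats=1, seed=0)
        # 2 hidden-unit values x 2x2 penalty combinations x 2 folds
        assert len(table) == 2 * 4 * 2

    def test_empty_grid_rejected(self):
        x, y = blobs(n=24)
        with pytest.raises(ValueError):
            grid_search(x, y, hu_grid=[], reg_grid=[0.01])
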