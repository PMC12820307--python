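"""LSTM regressor: architecture, gradients, packed-sequence semantics,
training dynamics."""

import numpy as np
import pytest

from kin2emg.model import (
    InvalidArgumentError,
    ModelConfig,
    backward,
    build_model,
    forward,
    masked_mse_loss,
    predict,
    train,
)


def _toy_sequences(rng, n, t_range=(20, 40), width=7, channels=8):
    W = (rng.standard_normal((width, channels)) * 0.4).astype(np.float32)
    seqs = []
    for _ in range(n):
        T = int(rng.integers(*t_range))
        X = rng.standard_normal((T, width)).astype(np.float32)
        Y = np.tanh(X @ W)
        seqs.append((X, Y))
    return seqs


class TestBuildModel:
    @pytest.mark.parametrize("width", [7, 8])
    def test_first_layer_input_dimension(self, width):
        net = build_model(ModelConfig(input_width=width))
        assert net.params["Wx0"].shape == (width, 4 * 128)
        assert net.params["Wh1"].shape == (64, 4 * 64)
        assert net.params["Wy"].shape == (64, 8)

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ModelConfig(input_width=5)

    def test_seeded_init_is_deterministic(self):
        a = build_model(ModelConfig(seed=11))
        b = build_model(ModelConfig(seed=11))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        c = build_model(ModelConfig(seed=12))
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


class TestPackedSemantics:
    def test_loss_denominator_counts_valid_timesteps_only(self):
        # batch of lengths 40 and 60: denominator is 100 timesteps, not 120
        rng = np.random.default_rng(0)
        pred = rng.standard_normal((2, 60, 8))
        target = np.zeros((2, 60, 8))
        mask = np.zeros((2, 60))
        mask[0, :40] = 1
        mask[1, :60] = 1
        loss, grad = masked_mse_loss(pred, target, mask)
        manual = (np.sum(pred[0, :40] ** 2) + np.sum(pred[1] ** 2)) / (100 * 8)
        assert loss == pytest.approx(manual, rel=1e-12)
        assert np.all(grad[0, 40:] == 0)

    def test_padding_does_not_change_prediction(self):
        # running a short sequence inside a padded batch equals running it alone
        cfg = ModelConfig(input_width=7, hidden_sizes=(6, 5), dropout_rate=0.0,
                          dtype="float64", seed=2)
        net = build_model(cfg)
        rng = np.random.default_rng(1)
        x_short = rng.standard_normal((13, 7))
        x = np.zeros((2, 30, 7))
        x[0, :13] = x_short
        x[1] = rng.standard_normal((30, 7))
        mask = np.zeros((2, 30))
        mask[0, :13] = 1
        mask[1, :] = 1
        batched, _ = forward(net.params, cfg, x, mask)
        alone, _ = forward(net.params, cfg, x_short[None], np.ones((1, 13)))
        np.testing.assert_allclose(batched[0, :13], alone[0], atol=1e-12)

    def test_gradients_match_numerical_differentiation(self):
        cfg = ModelConfig(input_width=7, output_width=3, hidden_sizes=(5, 4),
                          dropout_rate=0.0, dtype="float64", seed=3)
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 9, 7))
        y = rng.standard_normal((2, 9, 3))
        mask = np.ones((2, 9))
        mask[1, 5:] = 0

        def loss_at(params):
            pred, _ = forward(params, cfg, x, mask)
            return masked_mse_loss(pred, y, mask)[0]

        pred, caches = forward(net.params, cfg, x, mask)
        _, dy = masked_mse_loss(pred, y, mask)
        grads = backward(net.params, cfg, caches, dy)
        rng2 = np.random.default_rng(42)
        for k, g in grads.items():
            p = net.params[k]
            flat = p.reshape(-1)
            for idx in rng2.choice(p.size, size=min(12, p.size), replace=False):
                eps = 1e-6
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss_at(net.params)
                flat[idx] = old - eps
                lm = loss_at(net.params)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_overfits_single_sequence(self):
        rng = np.random.default_rng(5)
        seqs = _toy_sequences(rng, 1, t_range=(30, 31))
        cfg = ModelConfig(input_width=7, hidden_sizes=(16, 8), dropout_rate=0.0,
                          max_epochs=500, patience=500, learning_rate=1e-2, seed=4)
        trained = train(build_model(cfg), seqs, seqs, cfg)
        assert trained.history[-1]["train_loss"] < 1e-3

    def test_early_stopping_contract(self):
        # zero learning rate: validation never improves after epoch 1, so
        # training stops at epoch 1 + patience with best epoch 1
        rng = np.random.default_rng(6)
        seqs = _toy_sequences(rng, 3)
        cfg = ModelConfig(input_width=7, hidden_sizes=(6, 5), learning_rate=0.0,
                          max_epochs=100, patience=4, seed=7)
        trained = train(build_model(cfg), seqs, seqs[:1], cfg)
        assert trained.best_epoch == 1
        assert len(trained.history) == 1 + 4

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(8)
        seqs = _toy_sequences(rng, 6)
        cfg = ModelConfig(input_width=7, hidden_sizes=(8, 6), max_epochs=5,
                          patience=5, seed=9)
        h1 = train(build_model(cfg), seqs[:4], seqs[4:], cfg).history
        h2 = train(build_model(cfg), seqs[:4], seqs[4:], cfg).history
        assert [e["train_loss"] for e in h1] == [e["train_loss"] for e in h2]
        assert [e["val_loss"] for e in h1] == [e["val_loss"] for e in h2]

    def test_empty_training_set_rejected(self):
        cfg = ModelConfig(input_width=7)
        with pytest.raises(InvalidArgumentError):
            train(build_model(cfg), [], [], cfg)

    def test_width_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        seqs = _toy_sequences(rng, 2, width=8)
        cfg = ModelConfig(input_width=7, hidden_sizes=(6, 5))
        with pytest.raises(InvalidArgumentError):
            train(build_model(cfg), seqs, seqs, cfg)


@pytest.fixture(scope="module")
def tiny_trained():
    rng = np.random.default_rng(10)
    seqs = _toy_sequences(rng, 5)
    cfg = ModelConfig(input_width=7, hidden_sizes=(8, 6), max_epochs=10,
                      patience=10, seed=1)
    return train(build_model(cfg), seqs[:4], seqs[4:], cfg)


class TestPredict:
    def test_output_shape(self, tiny_trained):
        x = np.random.default_rng(0).standard_normal((37, 7))
        assert predict(tiny_trained, x).shape == (37, 8)

    def test_inference_deterministic(self, tiny_trained):
        x = np.random.default_rng(0).standard_normal((20, 7))
        np.testing.assert_array_equal(predict(tiny_trained, x), predict(tiny_trained, x))

    def test_width_mismatch(self, tiny_trained):
        with pytest.raises(InvalidArgumentError):
            predict(tiny_trained, np.zeros((10, 8)))

    def test_segment_predictions_concatenate_to_whole_length(self, tiny_trained):
        x = np.random.default_rng(2).standard_normal((50, 7))
        parts = [predict(tiny_trained, x[a:b]) for a, b in ((0, 20), (20, 35), (35, 50))]
        assert np.vstack(parts).shape == (50, 8)
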