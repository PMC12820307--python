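"""LSTM sequence regressor mapping kinematic features to 8-channel activity.

Architecture: input (7 or 8 features per frame) -> LSTM(128) -> dropout ->
LSTM(64) -> linear(8), trained with mean squared error on normalized
activation envelopes, mini-batches of 16 variable-length sequences, Adam,
and early stopping on a validation set with best-epoch parameter restore.

The implementation is pure numpy. Variable-length sequences in a batch are
padded to the batch maximum and masked so that padded timesteps contribute
neither to the recurrent state (the hidden and cell states freeze once a
sequence ends) nor to the loss denominator — the same contract as packed
sequences in the major deep-learning frameworks. Gradients are computed by
full backpropagation through time and are verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class InvalidArgumentError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the sequence regressor.

    Defaults follow the tuned architecture: two recurrent layers of 128 and
    64 units, dropout 0.2 between them, batches of 16 sequences, Adam at
    1e-3, early stopping with patience 20.
    """

    input_width: int = 7
    output_width: int = 8
    hidden_sizes: tuple = (128, 64)
    dropout_rate: float = 0.2
    batch_size: int = 16
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 20
    grad_clip: float = 5.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.input_width not in (7, 8):
            raise InvalidArgumentError("input_width must be 7 or 8")
        if not (0 <= self.dropout_rate < 1):
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")


# gate layout in the 4H axis: [input, forget, output, tanh-candidate]


class SequenceRegressor:
    """Untrained or trained LSTM regressor; parameters live in ``params``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = self._init_params()

    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        dt = np.dtype(cfg.dtype)
        params = {}
        in_size = cfg.input_width
        for layer, h in enumerate(cfg.hidden_sizes):
            k = 1.0 / np.sqrt(h)
            params[f"Wx{layer}"] = rng.uniform(-k, k, (in_size, 4 * h)).astype(dt)
            params[f"Wh{layer}"] = rng.uniform(-k, k, (h, 4 * h)).astype(dt)
            b = rng.uniform(-k, k, 4 * h).astype(dt)
            b[h : 2 * h] += 1.0  # forget-gate bias offset for gradient flow
            params[f"b{layer}"] = b
            in_size = h
        k = 1.0 / np.sqrt(in_size)
        params["Wy"] = rng.uniform(-k, k, (in_size, cfg.output_width)).astype(dt)
        params["by"] = rng.uniform(-k, k, cfg.output_width).astype(dt)
        return params


def build_model(config: ModelConfig) -> SequenceRegressor:
    """Instantiate the regressor with seeded parameter initialization."""
    return SequenceRegressor(config)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _lstm_forward(Wx, Wh, b, x, mask):
    """Masked LSTM layer forward.

    x: (B, T, F); mask: (B, T) in {0, 1}. Once a sequence's mask drops to
    zero its hidden and cell state freeze, so padded steps perform no
    recurrent update. The input projection x @ Wx is hoisted out of the
    recurrence as one large matmul.
    """
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    hs = np.empty((B, T, H), dtype=x.dtype)
    xp = x.reshape(B * T, -1) @ Wx
    xp = xp.reshape(B, T, 4 * H) + b
    cache = []
    for t in range(T):
        m = mask[:, t][:, None]
        a = xp[:, t] + h @ Wh
        ifo = expit(a[:, : 3 * H])
        i = ifo[:, :H]
        f = ifo[:, H : 2 * H]
        o = ifo[:, 2 * H :]
        g = np.tanh(a[:, 3 * H :])
        c_tilde = f * c + i * g
        tanh_c = np.tanh(c_tilde)
        h_tilde = o * tanh_c
        c_new = m * c_tilde + (1 - m) * c
        h_new = m * h_tilde + (1 - m) * h
        cache.append((h, c, i, f, g, o, tanh_c, m))
        h, c = h_new, c_new
        hs[:, t] = h
    return hs, cache


def _lstm_backward(Wx, Wh, x, dhs, cache):
    """Backprop through the masked LSTM layer. Returns (dx, dWx, dWh, db).

    Per-step work is limited to the recurrent couplings; gate-gradient
    projections onto Wx and the input are batched after the loop.
    """
    B, T, F = x.shape
    H = Wh.shape[0]
    da_all = np.empty((B, T, 4 * H), dtype=x.dtype)
    dWh = np.zeros_like(Wh)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tanh_c, m = cache[t]
        dh = dhs[:, t] + dh_next
        dc = dc_next
        dh_tilde = m * dh
        dh_carry = (1 - m) * dh
        dc_tilde = m * dc + dh_tilde * o * (1.0 - tanh_c**2)
        dc_carry = (1 - m) * dc
        da = da_all[:, t]
        di = dc_tilde * g
        df = dc_tilde * c_prev
        dg = dc_tilde * i
        do = dh_tilde * tanh_c
        np.multiply(di * i, 1 - i, out=da[:, :H])
        np.multiply(df * f, 1 - f, out=da[:, H : 2 * H])
        np.multiply(do * o, 1 - o, out=da[:, 2 * H : 3 * H])
        np.multiply(dg, 1 - g**2, out=da[:, 3 * H :])
        dWh += h_prev.T @ da
        dh_next = da @ Wh.T + dh_carry
        dc_next = dc_tilde * f + dc_carry
    flat_da = da_all.reshape(B * T, 4 * H)
    dx = (flat_da @ Wx.T).reshape(B, T, F)
    dWx = x.reshape(B * T, F).T @ flat_da
    db = da_all.sum(axis=(0, 1))
    return dx, dWx, dWh, db


def forward(
    params: dict,
    config: ModelConfig,
    x: np.ndarray,
    mask: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
):
    """Full forward pass. Returns (predictions (B, T, C), caches)."""
    caches = {"inputs": [x], "lstm": [], "dropout": []}
    h = x
    n_layers = len(config.hidden_sizes)
    for layer in range(n_layers):
        hs, cache = _lstm_forward(
            params[f"Wx{layer}"], params[f"Wh{layer}"], params[f"b{layer}"], h, mask
        )
        caches["lstm"].append(cache)
        if layer < n_layers - 1 and config.dropout_rate > 0 and dropout_rng is not None:
            keep = 1.0 - config.dropout_rate
            dmask = (dropout_rng.random(hs.shape) < keep).astype(hs.dtype) / keep
            hs = hs * dmask
            caches["dropout"].append(dmask)
        else:
            caches["dropout"].append(None)
        caches["inputs"].append(hs)
        h = hs
    y = h @ params["Wy"] + params["by"]
    caches["top"] = h
    return y, caches


def masked_mse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    """MSE over valid timesteps only.

    The denominator is (number of valid timesteps) x (channels): a batch of
    lengths 40 and 60 divides by 100 timesteps, not by the padded 120.
    Returns (loss, dloss/dpred).
    """
    m = mask[:, :, None]
    n_valid = mask.sum()
    if n_valid == 0:
        raise ValueError("batch contains no valid timesteps")
    denom = n_valid * pred.shape[2]
    diff = (pred - target) * m
    loss = float(np.sum(diff**2) / denom)
    return loss, (2.0 / denom) * diff


def backward(params, config, caches, dy):
    grads = {}
    top = caches["top"]
    grads["Wy"] = np.einsum("btf,btc->fc", top, dy)
    grads["by"] = dy.sum(axis=(0, 1))
    dh = dy @ params["Wy"].T
    for layer in range(len(config.hidden_sizes) - 1, -1, -1):
        dmask = caches["dropout"][layer]
        if dmask is not None:
            dh = dh * dmask
        x_in = caches["inputs"][layer]
        dh, dWx, dWh, db = _lstm_backward(
            params[f"Wx{layer}"], params[f"Wh{layer}"], x_in, dh, caches["lstm"][layer]
        )
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"b{layer}"] = db
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Fitted regressor with its training history."""

    params: dict
    config: ModelConfig
    history: list  # per-epoch dicts: {"epoch", "train_loss", "val_loss"}
    best_epoch: int
    seed: int


def _pad_batch(seqs_x, seqs_y, dtype):
    lengths = [len(x) for x in seqs_x]
    B, T = len(seqs_x), max(lengths)
    F = seqs_x[0].shape[1]
    C = seqs_y[0].shape[1]
    x = np.zeros((B, T, F), dtype=dtype)
    y = np.zeros((B, T, C), dtype=dtype)
    mask = np.zeros((B, T), dtype=dtype)
    for b, (xs, ys) in enumerate(zip(seqs_x, seqs_y)):
        x[b, : len(xs)] = xs
        y[b, : len(ys)] = ys
        mask[b, : len(xs)] = 1.0
    return x, y, mask


def _batched_loss(params, config, sequences, dtype):
    """Loss over a sequence set without dropout, weighted by valid timesteps."""
    total, weight = 0.0, 0.0
    for start in range(0, len(sequences), config.batch_size):
        chunk = sequences[start : start + config.batch_size]
        x, y, mask = _pad_batch([s[0] for s in chunk], [s[1] for s in chunk], dtype)
        pred, _ = forward(params, config, x, mask, dropout_rng=None)
        loss, _ = masked_mse_loss(pred, y, mask)
        w = mask.sum()
        total += loss * w
        weight += w
    return total / weight


def _epoch_batches(lengths, batch_size, rng):
    """Length-bucketed mini-batches: shuffle, sort within windows of four
    batches, cut, then shuffle batch order. Keeps batch composition varying
    across epochs while limiting the padding overhead of mixing long and
    short sequences."""
    order = rng.permutation(len(lengths))
    window = 4 * batch_size
    batches = []
    for start in range(0, len(order), window):
        w = order[start : start + window]
        w = w[np.argsort(lengths[w], kind="stable")]
        for b in range(0, len(w), batch_size):
            batches.append(w[b : b + batch_size])
    return [batches[i] for i in rng.permutation(len(batches))]


def _clip_grads(grads, max_norm):
    if max_norm is None or max_norm <= 0:
        return grads
    norm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
    if norm > max_norm:
        scale = max_norm / norm
        grads = {k: g * scale for k, g in grads.items()}
    return grads


def train(
    model: SequenceRegressor,
    train_sequences: list,
    val_sequences: list,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit the regressor with Adam, early stopping on validation loss.

    ``train_sequences`` / ``val_sequences`` are lists of ``(X, Y)`` pairs
    with ``X`` of shape (T, input_width) and ``Y`` of shape (T, 8); lengths
    may differ between sequences. Training stops when the validation loss
    has not improved for ``patience`` epochs and the best-epoch parameters
    are restored. Fully deterministic given the config seed.
    """
    config = config or model.config
    if not train_sequences:
        raise InvalidArgumentError("empty training set")
    if not val_sequences:
        raise InvalidArgumentError("need at least one validation sequence")
    widths = {s[0].shape[1] for s in train_sequences + val_sequences}
    if widths != {config.input_width}:
        raise InvalidArgumentError(
            f"feature widths {widths} do not match input_width {config.input_width}"
        )
    dt = np.dtype(config.dtype)
    train_seqs = [(np.asarray(x, dt), np.asarray(y, dt)) for x, y in train_sequences]
    val_seqs = [(np.asarray(x, dt), np.asarray(y, dt)) for x, y in val_sequences]
    val_seqs.sort(key=lambda s: len(s[0]))  # homogeneous-length eval batches

    params = model.params
    rng = np.random.default_rng(config.seed + 1)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = []
    best_val = np.inf
    best_epoch = -1
    best_params = None
    lengths = np.array([len(x) for x, _ in train_seqs])
    for epoch in range(1, config.max_epochs + 1):
        total, weight = 0.0, 0.0
        for idx in _epoch_batches(lengths, config.batch_size, rng):
            x, y, mask = _pad_batch(
                [train_seqs[i][0] for i in idx], [train_seqs[i][1] for i in idx], dt
            )
            pred, caches = forward(params, config, x, mask, dropout_rng=rng)
            loss, dy = masked_mse_loss(pred, y, mask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch of {len(idx)} sequences); try a lower learning rate"
                )
            grads = backward(params, config, caches, dy)
            grads = _clip_grads(grads, config.grad_clip)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                params[k] = params[k] - config.learning_rate * (
                    (adam_m[k] / bc1) / (np.sqrt(adam_v[k] / bc2) + eps)
                ).astype(params[k].dtype)
            w = mask.sum()
            total += loss * w
            weight += w
        val_loss = _batched_loss(params, config, val_seqs, dt)
        history.append(
            {"epoch": epoch, "train_loss": total / weight, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = copy.deepcopy(params)
        elif epoch - best_epoch >= config.patience:
            break
    model.params = best_params if best_params is not None else params
    return TrainedModel(
        params=model.params,
        config=config,
        history=history,
        best_epoch=best_epoch,
        seed=config.seed,
    )


def predict(trained: TrainedModel | SequenceRegressor, features: np.ndarray) -> np.ndarray:
    """Predict the 8-channel activity sequence for one feature sequence.

    Inference is deterministic (dropout off); the linear head is not
    clamped, so predictions may overshoot the [0, 1] envelope range.
    """
    config = trained.config
    params = trained.params
    x = np.asarray(features, dtype=np.dtype(config.dtype))
    if x.ndim != 2 or x.shape[1] != config.input_width:
        raise InvalidArgumentError(
            f"expected (T, {config.input_width}) features, got {x.shape}"
        )
    mask = np.ones((1, x.shape[0]), dtype=x.dtype)
    pred, _ = forward(params, config, x[None], mask, dropout_rng=None)
    return pred[0].astype(float)
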