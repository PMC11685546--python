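"""Multi-branch ("stacked") 1-D convolutional network in NumPy.

Each input channel (by default the three acceleration axes and the three
orientation angles) enters its own convolutional sub-model:

    conv(32 filters, kernel 16) -> batch-norm -> ReLU -> maxpool(2)
    conv(16 filters, kernel 16) -> batch-norm -> ReLU -> maxpool(2)

The flattened sub-model outputs are concatenated, passed through dropout
(p = 0.25) and a dense softmax head.  Training uses Adam (lr 0.001),
batch size 32, categorical cross-entropy, early stopping on validation
accuracy with best-weight restoration.

Keeping channels in separate pathways stops dissimilar channels (linear
acceleration vs. tilt angle) from being mixed in the first layer, which
is what distinguishes this architecture from a conventional single-stem
CNN.  The implementation is deliberately self-contained and exactly
reproducible: all randomness (initialization, shuffling, dropout,
validation split) flows from one seeded generator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_CHANNELS = ("ax", "ay", "az", "angle_x", "angle_y", "angle_z")


class ShapeError(ValueError):
    """Input too short for the configured convolution/pooling stack."""


@dataclass(frozen=True)
class SCNNConfig:
    """Hyperparameters of the stacked CNN.

    ``branch_mode="per-channel"`` gives one univariate branch per named
    channel; ``"grouped"`` gives two three-channel branches (acceleration
    and angle), the alternative reading of the architecture.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    conv1_filters: int = 32
    conv1_kernel: int = 16
    conv2_filters: int = 16
    conv2_kernel: int = 16
    pool_size: int = 2
    dropout: float = 0.25
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 100
    val_fraction: float = 0.2
    branch_mode: str = "per-channel"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.branch_mode not in ("per-channel", "grouped"):
            raise ValueError("branch_mode must be 'per-channel' or 'grouped'")
        if self.branch_mode == "grouped" and len(self.channels) % 3:
            raise ValueError("grouped mode needs a multiple of 3 channels")

    def branch_channel_indices(self) -> list[list[int]]:
        n = len(self.channels)
        if self.branch_mode == "per-channel":
            return [[i] for i in range(n)]
        return [list(range(i, i + 3)) for i in range(0, n, 3)]


# ---------------------------------------------------------------- layers


def _conv1d_forward(x, W, b):
    # x (N, L, Cin), W (K, Cin, F) -> (N, L-K+1, F)
    K = W.shape[0]
    win = sliding_window_view(x, K, axis=1)  # (N, Lo, Cin, K)
    out = np.einsum("nlck,kcf->nlf", win, W, optimize=True) + b
    return out, (x, win, W)


def _conv1d_backward(dout, cache):
    x, win, W = cache
    K = W.shape[0]
    dW = np.einsum("nlck,nlf->kcf", win, dout, optimize=True)
    db = dout.sum(axis=(0, 1))
    dx = np.zeros_like(x)
    Lo = dout.shape[1]
    for k in range(K):
        dx[:, k:k + Lo, :] += dout @ W[k].T
    return dx, dW, db


def _bn_forward(x, gamma, beta, running, training, momentum=0.9, eps=1e-5):
    # normalize per channel over batch and length axes
    if training:
        mean = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv
    return xhat * gamma + beta, (xhat, inv, gamma, x.shape[0] * x.shape[1])


def _bn_backward(dout, cache):
    xhat, inv, gamma, m = cache
    dgamma = (dout * xhat).sum(axis=(0, 1))
    dbeta = dout.sum(axis=(0, 1))
    dxhat = dout * gamma
    dx = inv / m * (m * dxhat - dxhat.sum(axis=(0, 1))
                    - xhat * (dxhat * xhat).sum(axis=(0, 1)))
    return dx, dgamma, dbeta


def _pool_forward(x, size):
    N, L, C = x.shape
    Lo = L // size
    if Lo < 1:
        raise ShapeError("sequence collapsed to zero length at a pooling layer")
    xt = x[:, :Lo * size, :].reshape(N, Lo, size, C)
    idx = xt.argmax(axis=2)
    out = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx, x.shape, size)


def _pool_backward(dout, cache):
    idx, shape, size = cache
    N, L, C = shape
    Lo = dout.shape[1]
    dxt = np.zeros((N, Lo, size, C), dtype=dout.dtype)
    np.put_along_axis(dxt, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :Lo * size, :] = dxt.reshape(N, Lo * size, C)
    return dx


# ----------------------------------------------------------------- model


class StackedCNN:
    """Multi-branch 1-D CNN classifier over fixed-length channel tensors."""

    def __init__(self, config: SCNNConfig, seq_len: int, n_classes: int,
                 classes: list[str] | None = None):
        self.config = config
        self.seq_len = seq_len
        self.n_classes = n_classes
        self.classes = classes
        self._check_length(seq_len)
        self.rng = np.random.default_rng(config.seed)
        self.params: dict = {}
        self.running: dict = {}
        self._build()
        self._opt_state = None
        self.history: dict = {}

    # -- architecture ----------------------------------------------------

    def _flat_len(self, L: int) -> int:
        c = self.config
        l1 = L - c.conv1_kernel + 1
        if l1 < 1:
            return -1
        p1 = l1 // c.pool_size
        l2 = p1 - c.conv2_kernel + 1
        if l2 < 1:
            return -1
        p2 = l2 // c.pool_size
        return p2 if p2 >= 1 else -1

    def _check_length(self, L: int) -> None:
        if self._flat_len(L) > 0:
            return
        m = L
        while self._flat_len(m) < 1:
            m += 1
        raise ShapeError(
            f"sequence length {L} too short for two kernel-"
            f"{self.config.conv1_kernel}/{self.config.conv2_kernel} conv "
            f"blocks with pool {self.config.pool_size}; minimum is {m}")

    def _build(self) -> None:
        c = self.config
        self.branches = c.branch_channel_indices()
        out_per_branch = self._flat_len(self.seq_len) * c.conv2_filters
        for bi, chans in enumerate(self.branches):
            cin = len(chans)
            self.params[f"b{bi}_W1"] = self._he((c.conv1_kernel, cin, c.conv1_filters))
            self.params[f"b{bi}_b1"] = np.zeros(c.conv1_filters)
            self.params[f"b{bi}_g1"] = np.ones(c.conv1_filters)
            self.params[f"b{bi}_be1"] = np.zeros(c.conv1_filters)
            self.params[f"b{bi}_W2"] = self._he(
                (c.conv2_kernel, c.conv1_filters, c.conv2_filters))
            self.params[f"b{bi}_b2"] = np.zeros(c.conv2_filters)
            self.params[f"b{bi}_g2"] = np.ones(c.conv2_filters)
            self.params[f"b{bi}_be2"] = np.zeros(c.conv2_filters)
            self.running[f"b{bi}_1"] = {"mean": np.zeros(c.conv1_filters),
                                        "var": np.ones(c.conv1_filters)}
            self.running[f"b{bi}_2"] = {"mean": np.zeros(c.conv2_filters),
                                        "var": np.ones(c.conv2_filters)}
        concat = out_per_branch * len(self.branches)
        self.params["Wd"] = self._he((concat, self.n_classes))
        self.params["bd"] = np.zeros(self.n_classes)

    def _he(self, shape) -> np.ndarray:
        fan_in = int(np.prod(shape[:-1]))
        return self.rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

    # -- forward / backward ----------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None):
        """Class probabilities for X of shape (N, seq_len, n_channels)."""
        c = self.config
        caches, flats = [], []
        for bi, chans in enumerate(self.branches):
            x = X[:, :, chans]
            z1, cv1 = _conv1d_forward(x, self.params[f"b{bi}_W1"],
                                      self.params[f"b{bi}_b1"])
            n1, cb1 = _bn_forward(z1, self.params[f"b{bi}_g1"],
                                  self.params[f"b{bi}_be1"],
                                  self.running[f"b{bi}_1"], training)
            r1 = np.maximum(n1, 0.0)
            p1, cp1 = _pool_forward(r1, c.pool_size)
            z2, cv2 = _conv1d_forward(p1, self.params[f"b{bi}_W2"],
                                      self.params[f"b{bi}_b2"])
            n2, cb2 = _bn_forward(z2, self.params[f"b{bi}_g2"],
                                  self.params[f"b{bi}_be2"],
                                  self.running[f"b{bi}_2"], training)
            r2 = np.maximum(n2, 0.0)
            p2, cp2 = _pool_forward(r2, c.pool_size)
            flats.append(p2.reshape(len(X), -1))
            caches.append((cv1, cb1, n1, cp1, cv2, cb2, n2, cp2, p2.shape))
        h = np.concatenate(flats, axis=1)
        if training and c.dropout > 0:
            rng = dropout_rng if dropout_rng is not None else self.rng
            mask = (rng.random(h.shape) >= c.dropout) / (1.0 - c.dropout)
        else:
            mask = None
        hd = h * mask if mask is not None else h
        logits = hd @ self.params["Wd"] + self.params["bd"]
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        cache = (caches, h, mask, hd, probs)
        return probs, cache

    def backward(self, y_onehot: np.ndarray, cache) -> dict:
        caches, h, mask, hd, probs = cache
        c = self.config
        N = len(y_onehot)
        grads = {}
        dlogits = (probs - y_onehot) / N
        grads["Wd"] = hd.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wd"].T
        if mask is not None:
            dh = dh * mask
        offset = 0
        for bi, _ in enumerate(self.branches):
            cv1, cb1, n1, cp1, cv2, cb2, n2, cp2, p2shape = caches[bi]
            width = int(np.prod(p2shape[1:]))
            dp2 = dh[:, offset:offset + width].reshape(p2shape)
            offset += width
            dr2 = _pool_backward(dp2, cp2)
            dn2 = dr2 * (n2 > 0)
            dz2, dg2, dbe2 = _bn_backward(dn2, cb2)
            dp1, dW2, db2 = _conv1d_backward(dz2, cv2)
            dr1 = _pool_backward(dp1, cp1)
            dn1 = dr1 * (n1 > 0)
            dz1, dg1, dbe1 = _bn_backward(dn1, cb1)
            _, dW1, db1 = _conv1d_backward(dz1, cv1)
            grads[f"b{bi}_W1"], grads[f"b{bi}_b1"] = dW1, db1
            grads[f"b{bi}_g1"], grads[f"b{bi}_be1"] = dg1, dbe1
            grads[f"b{bi}_W2"], grads[f"b{bi}_b2"] = dW2, db2
            grads[f"b{bi}_g2"], grads[f"b{bi}_be2"] = dg2, dbe2
        return grads

    # -- training --------------------------------------------------------

    def _adam_step(self, grads: dict) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        if self._opt_state is None:
            self._opt_state = {"t": 0,
                               "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                               "v": {k: np.zeros_like(v) for k, v in self.params.items()}}
        st = self._opt_state
        st["t"] += 1
        t = st["t"]
        for k, g in grads.items():
            st["m"][k] = b1 * st["m"][k] + (1 - b1) * g
            st["v"][k] = b2 * st["v"][k] + (1 - b2) * g * g
            mhat = st["m"][k] / (1 - b1 ** t)
            vhat = st["v"][k] / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> dict:
        """Train with Adam and early stopping on validation accuracy.

        ``y`` holds integer class indices.  If no validation data is
        supplied, a stratified ``val_fraction`` split is carved from the
        training set.  The best-validation weights are restored at the
        end.  Returns the per-epoch history.
        """
        c = self.config
        if X_val is None:
            X, y, X_val, y_val = _stratified_split(X, y, c.val_fraction, self.rng)
        onehot = np.eye(self.n_classes)[y]
        n = len(X)
        best_acc, best_params, best_running = -1.0, None, None
        wait = 0
        history = {"loss": [], "val_accuracy": []}
        for epoch in range(c.max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                probs, cache = self.forward(X[idx], training=True)
                loss = -np.mean(np.log(np.clip(
                    probs[np.arange(len(idx)), y[idx]], 1e-12, None)))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf loss at epoch {epoch}, batch offset {start}")
                epoch_loss += loss * len(idx)
                grads = self.backward(onehot[idx], cache)
                self._adam_step(grads)
            val_acc = float(np.mean(self.predict(X_val) == y_val))
            history["loss"].append(epoch_loss / n)
            history["val_accuracy"].append(val_acc)
            if val_acc > best_acc:
                best_acc, wait = val_acc, 0
                best_params = copy.deepcopy(self.params)
                best_running = copy.deepcopy(self.running)
            else:
                wait += 1
                if wait >= c.patience:
                    break
        if best_params is not None:
            self.params, self.running = best_params, best_running
        self.history = history
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(X, training=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def _stratified_split(X, y, fraction, rng):
    """Per-class shuffled split; at least one validation sample per class."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[:k])
        train_idx.extend(idx[k:])
    train_idx, val_idx = np.array(train_idx), np.array(val_idx)
    return X[train_idx], y[train_idx], X[val_idx], y[val_idx]


def build_scnn(config: SCNNConfig, seq_len: int, n_classes: int,
               classes: list[str] | None = None) -> StackedCNN:
    """Construct a seeded, untrained stacked CNN for the given input shape."""
    return StackedCNN(config, seq_len, n_classes, classes)


def train_scnn(model: StackedCNN, X: np.ndarray, y: np.ndarray,
               X_val: np.ndarray | None = None,
               y_val: np.ndarray | None = None) -> tuple[StackedCNN, dict]:
    """Train ``model`` in place; returns (model, history)."""
    history = model.fit(X, y, X_val, y_val)
    return model, history
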