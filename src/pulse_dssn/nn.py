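"""Minimal feed-forward / 1-D convolutional network engine (numpy, CPU).

Supports exactly what the pulse classifiers need: 1-D convolution (valid
padding, im2col), ReLU, max-pooling of size 2, dropout, dense layers, a
softmax cross-entropy head, and SGD with momentum and L2 weight decay.
Training uses mini-batches with per-epoch shuffling and early stopping on
validation loss: when the validation loss has not decreased for ``patience``
epochs, training stops and the weights with the smallest validation loss
are restored.

All computation is float32; all randomness (weight init, shuffling,
dropout masks) comes from one seeded generator, so a fit is bit-reproducible
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "TrainLog",
]

F32 = np.float32


class Layer:
    """Base layer: forward/backward plus (param, grad, velocity) triples."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[list[np.ndarray]]:
        return []


class Conv1D(Layer):
    """Valid 1-D convolution: (N, C_in, L) -> (N, C_out, L - k + 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        W = rng.normal(0.0, scale, (fan_in, out_channels))
        # zero-mean filters: inputs are non-negative ([0,1] cycles, ReLU
        # outputs), so a filter whose weights sum negative is born dead and
        # ReLU makes the whole stack unrecoverable for unlucky seeds
        self.W = (W - W.mean(axis=0, keepdims=True)).astype(F32)
        self.b = np.zeros(out_channels, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (N, C, L) -> windows (N, L_out, C*k)
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        # win: (N, C, L_out, k) -> (N, L_out, C, k)
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.cin * self.k
        )
        self._col = col if train else None
        self._in_len = x.shape[2]
        y = col @ self.W + self.b  # (N, L_out, C_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # grad: (N, C_out, L_out) -> (N, L_out, C_out)
        g = np.ascontiguousarray(grad.transpose(0, 2, 1))
        col = self._col
        self.gW += np.tensordot(col, g, axes=([0, 1], [0, 1]))
        self.gb += g.sum(axis=(0, 1))
        dcol = g @ self.W.T  # (N, L_out, C*k)
        n, l_out = dcol.shape[0], dcol.shape[1]
        dcol = dcol.reshape(n, l_out, self.cin, self.k).transpose(0, 2, 1, 3)
        dx = np.zeros((n, self.cin, self._in_len), dtype=F32)
        for t in range(self.k):
            dx[:, :, t : t + l_out] += dcol[:, :, :, t]
        return dx

    def params(self):
        return [[self.W, self.gW, self.vW], [self.b, self.gb, self.vb]]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, grad):
        return np.where(self._mask, grad, F32(0.0))


class MaxPool1D(Layer):
    """Non-overlapping max pooling of size 2 (odd trailing sample dropped)."""

    def forward(self, x, train):
        l = x.shape[2]
        l2 = l // 2
        self._in_len = l
        a = x[:, :, 0 : 2 * l2 : 2]
        b = x[:, :, 1 : 2 * l2 : 2]
        self._left = a >= b
        return np.where(self._left, a, b)

    def backward(self, grad):
        n, c, l2 = grad.shape
        dx = np.zeros((n, c, self._in_len), dtype=F32)
        dx[:, :, 0 : 2 * l2 : 2] = np.where(self._left, grad, F32(0.0))
        dx[:, :, 1 : 2 * l2 : 2] = np.where(self._left, F32(0.0), grad)
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, (in_features, out_features)).astype(F32)
        self.b = np.zeros(out_features, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [[self.W, self.gW, self.vW], [self.b, self.gb, self.vb]]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainLog:
    """Per-epoch training record (losses are mean cross-entropy)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class Network:
    """A sequential network with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.log = TrainLog()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        out = [
            _softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.vstack(out) if out else np.empty((0, self._n_out()))

    def _n_out(self) -> int:
        for layer in reversed(self.layers):
            if isinstance(layer, Dense):
                return layer.W.shape[1]
        raise RuntimeError("network has no dense layer")

    def loss(self, x: np.ndarray, y_idx: np.ndarray, batch_size: int = 512) -> float:
        """Mean cross-entropy of integer class indices."""
        total, n = 0.0, x.shape[0]
        for i in range(0, n, batch_size):
            p = _softmax(self.forward(np.asarray(x[i : i + batch_size], dtype=F32)))
            idx = y_idx[i : i + batch_size]
            total += -np.sum(np.log(np.clip(p[np.arange(idx.size), idx], 1e-12, None)))
        return float(total / n)

    def _step(self, xb: np.ndarray, yb: np.ndarray, lr: float, momentum: float,
              weight_decay: float) -> float:
        logits = self.forward(xb, train=True)
        p = _softmax(logits)
        n = xb.shape[0]
        grad = p.copy()
        grad[np.arange(n), yb] -= 1.0
        grad = (grad / n).astype(F32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            for w, g, v in layer.params():
                g += weight_decay * w
                v *= momentum
                v -= lr * g
                w += v
                g[...] = 0.0
        ce = -np.mean(np.log(np.clip(p[np.arange(n), yb], 1e-12, None)))
        return float(ce)

    def fit(
        self,
        x: np.ndarray,
        y_idx: np.ndarray,
        x_val: np.ndarray,
        y_val_idx: np.ndarray,
        rng: np.random.Generator,
        batch_size: int = 8,
        lr: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 0.0001,
        max_epochs: int = 1000,
        patience: int = 10,
    ) -> TrainLog:
        """SGD training with early stopping on validation loss."""
        x = np.asarray(x, dtype=F32)
        x_val = np.asarray(x_val, dtype=F32)
        y_idx = np.asarray(y_idx)
        y_val_idx = np.asarray(y_val_idx)
        n = x.shape[0]
        best_val = np.inf
        best_state: list[np.ndarray] = []
        wait = 0
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                losses.append(self._step(x[idx], y_idx[idx], lr, momentum, weight_decay))
            val = self.loss(x_val, y_val_idx)
            self.log.train_loss.append(float(np.mean(losses)))
            self.log.val_loss.append(val)
            if val < best_val - 1e-7:
                best_val = val
                best_state = self._get_state()
                self.log.best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        self.log.stopped_epoch = len(self.log.val_loss) - 1
        if best_state:
            self._set_state(best_state)
        return self.log

    def _get_state(self) -> list[np.ndarray]:
        return [w.copy() for layer in self.layers for w, _, _ in layer.params()]

    def _set_state(self, state: list[np.ndarray]) -> None:
        flat = [w for layer in self.layers for w, _, _ in layer.params()]
        for w, saved in zip(flat, state):
            w[...] = saved
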