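"""A compact, deterministic feed-forward regressor in plain numpy.

Architecture: configurable hidden layers with batch normalization, ReLU and
inverted dropout after each hidden layer; linear output; mean-squared-error
loss trained with Adam on shuffled mini-batches. Batch statistics are
tracked with exponential moving averages for inference. All randomness
(initialization, shuffling, dropout masks) flows from a single seed, so two
trainings from the same seed are bitwise identical.

This is intentionally a small engine: a few dense layers on standardized
tabular features, which is all the parameter-surrogate task requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPConfig", "MLPRegressor"]


@dataclass(frozen=True)
class MLPConfig:
    hidden: tuple[int, ...] = (64, 64, 32, 16)
    dropout: float = 0.1
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 32
    bn_momentum: float = 0.9
    l2: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if len(self.hidden) < 1:
            raise ValueError("at least one hidden layer is required")


class _Dense:
    def __init__(self, n_in: int, n_out: int, rand: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialization for ReLU stacks
        self.w = rand.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.mw = np.zeros_like(self.w); self.vw = np.zeros_like(self.w)
        self.mb = np.zeros_like(self.b); self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray, l2: float) -> np.ndarray:
        self.gw = self.x.T @ grad + l2 * self.w
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def adam(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        for p, g, m, v in ((self.w, self.gw, self.mw, self.vw),
                           (self.b, self.gb, self.mb, self.vb)):
            m *= beta1; m += (1 - beta1) * g
            v *= beta2; v += (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class _BatchNorm:
    def __init__(self, n: int, momentum: float):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.mg = np.zeros(n); self.vg = np.zeros(n)
        self.mb = np.zeros(n); self.vb = np.zeros(n)
        self.eps = 1e-5

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)
        self.xhat = (x - mean) / self.std
        return self.gamma * self.xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.gg = (grad * self.xhat).sum(axis=0)
        self.gb = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=0) - self.xhat * (dxhat * self.xhat).mean(axis=0)) / self.std

    def adam(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        for p, g, m, v in ((self.gamma, self.gg, self.mg, self.vg),
                           (self.beta, self.gb, self.mb, self.vb)):
            m *= beta1; m += (1 - beta1) * g
            v *= beta2; v += (1 - beta2) * g**2
            p -= lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)


class MLPRegressor:
    """Multi-output feed-forward regressor; see module docstring."""

    def __init__(self, n_features: int, n_targets: int, config: MLPConfig | None = None,
                 seed: int = 0):
        self.config = config or MLPConfig()
        self.rand = np.random.default_rng(seed)
        sizes = [n_features, *self.config.hidden]
        self.dense = [_Dense(a, b, self.rand) for a, b in zip(sizes[:-1], sizes[1:])]
        self.bnorm = [_BatchNorm(b, self.config.bn_momentum) for b in sizes[1:]]
        self.head = _Dense(sizes[-1], n_targets, self.rand)
        self.loss_history: list[float] = []
        self._t = 0

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._relu_masks = []
        self._drop_masks = []
        h = x
        keep = 1.0 - self.config.dropout
        for dense, bn in zip(self.dense, self.bnorm):
            h = bn.forward(dense.forward(h), training)
            mask = h > 0
            h = h * mask
            self._relu_masks.append(mask)
            if training and self.config.dropout > 0:
                dmask = (self.rand.random(h.shape) < keep) / keep
                h = h * dmask
                self._drop_masks.append(dmask)
            else:
                self._drop_masks.append(None)
        return self.head.forward(h)

    def _backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad, self.config.l2)
        for dense, bn, relu, drop in zip(
            reversed(self.dense), reversed(self.bnorm),
            reversed(self._relu_masks), reversed(self._drop_masks),
        ):
            if drop is not None:
                g = g * drop
            g = g * relu
            g = dense.backward(bn.backward(g), self.config.l2)
        self._t += 1
        lr = getattr(self, "_lr", self.config.lr)
        for layer in (*self.dense, *self.bnorm, self.head):
            layer.adam(lr, self._t)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n = len(x)
        bs = min(self.config.batch_size, n)
        base_lr = self.config.lr
        for epoch in range(self.config.epochs):
            # step decay over the final fifth settles minibatch/dropout jitter
            lr = base_lr * (0.1 if epoch >= 0.8 * self.config.epochs else 1.0)
            self._lr = lr
            order = self.rand.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if len(idx) < 2:
                    continue  # batch norm needs at least two rows
                pred = self._forward(x[idx], training=True)
                err = pred - y[idx]
                epoch_loss += float(np.sum(err**2))
                self._backward(2.0 * err / err.size)
            self.loss_history.append(epoch_loss / n)
        self._recalibrate_batch_norm(x)
        return self

    def _recalibrate_batch_norm(self, x: np.ndarray) -> None:
        """Replace running batch-norm statistics with exact full-training-set
        statistics at the final weights (dropout off)."""
        h = x
        for dense, bn in zip(self.dense, self.bnorm):
            z = dense.forward(h)
            bn.run_mean = z.mean(axis=0)
            bn.run_var = z.var(axis=0)
            h = bn.forward(z, training=False)
            h = h * (h > 0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float), training=False)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        return float(np.mean((self.predict(x) - y) ** 2))
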