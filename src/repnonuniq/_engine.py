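"""Minimal numpy compute engine for small convolutional classifiers.

Layers implement ``forward(x, train)`` and ``backward(grad)`` with explicit
parameter gradients; convolution uses an im2col formulation.  Everything is
float64 and fully deterministic given the initialization RNG, which is what
the representation analyses downstream require.

Shapes follow the channels-first convention internally: (B, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "SGDMomentum",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer; parameter-free layers override forward/backward only."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) patch matrix with 'same' padding."""
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (B, C, H, W, k, k) -> (B, C*k*k, H*W)
    return (
        windows.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, H * W).copy()
    )


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the image."""
    B, C, H, W = shape
    p = k // 2
    out = np.zeros((B, C, H + 2 * p, W + 2 * p))
    cols = cols.reshape(B, C, k, k, H, W)
    for dy in range(k):
        for dx in range(k):
            out[:, :, dy : dy + H, dx : dx + W] += cols[:, :, dy, dx]
    return out[:, :, p : p + H, p : p + W]


class Conv2D(Layer):
    """k x k convolution with 'same' padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._shape = x.shape
        self._cols = _im2col(x, self.k)  # (B, Ckk, HW)
        B, _, H, W = x.shape
        out = np.einsum("fp,bpq->bfq", self.W, self._cols) + self.b[None, :, None]
        return out.reshape(B, self.out_ch, H, W)

    def backward(self, grad):
        B, F, H, W = grad.shape
        g = grad.reshape(B, F, H * W)
        self.dW[...] = np.einsum("bfq,bpq->fp", g, self._cols)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("fp,bfq->bpq", self.W, g)
        return _col2im(dcols, self._shape, self.k)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (B, H, W).

    Training mode normalizes with batch statistics and updates running
    averages; evaluation mode uses the frozen running statistics, so
    representation extraction is deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._train = train
        return (
            self.gamma[None, :, None, None] * self._xhat
            + self.beta[None, :, None, None]
        )

    def backward(self, grad):
        axes = (0, 2, 3)
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = self.gamma[None, :, None, None] * self._istd[None, :, None, None]
        if not self._train:
            return grad * g
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = grad.sum(axis=axes)[None, :, None, None]
        sum_gx = (grad * self._xhat).sum(axis=axes)[None, :, None, None]
        return g * (grad - sum_g / m - self._xhat * sum_gx / m)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        x = x[:, :, : 2 * H2, : 2 * W2]
        self._shape = (B, C, H, W)
        patches = (
            x.reshape(B, C, H2, 2, W2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H2, W2, 4)
        )
        self._idx = patches.argmax(axis=-1)  # ties -> lowest index
        return np.take_along_axis(patches, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, H, W = self._shape
        H2, W2 = H // 2, W // 2
        scatter = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(scatter, self._idx[..., None], grad[..., None], axis=-1)
        out = np.zeros((B, C, H, W))
        out[:, :, : 2 * H2, : 2 * W2] = (
            scatter.reshape(B, C, H2, W2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, 2 * H2, 2 * W2)
        )
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W


class SGDMomentum:
    """SGD with classical momentum and optional cosine learning-rate decay."""

    def __init__(self, layers: list[Layer], lr: float = 0.01, momentum: float = 0.9):
        self.layers = layers
        self.base_lr = lr
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for l in layers for p in l.params()]

    def set_cosine_lr(self, epoch: int, total_epochs: int) -> None:
        self.lr = self.base_lr * 0.5 * (1 + np.cos(np.pi * epoch / max(total_epochs, 1)))

    def step(self) -> None:
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                v = self.velocity[i]
                v *= self.momentum
                v -= self.lr * g
                p += v
                i += 1


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, dloss/dlogits); the gradient is already averaged over
    the batch.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    B = len(labels)
    loss = -np.mean(np.log(probs[np.arange(B), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(B), labels] -= 1.0
    return float(loss), grad / B
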