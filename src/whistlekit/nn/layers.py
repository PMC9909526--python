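"""Layers with explicit forward/backward passes.

All data flows as float32 arrays in NHWC layout.  Each layer is built
once against a known input shape (``build`` returns the output shape
and initializes parameters from the supplied RNG), caches what its
backward pass needs during ``forward(training=True)``, and accumulates
parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless by default, no parameters."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


class Conv2D(Layer):
    """Valid (unpadded) strided 2-D convolution with bias.

    Weights use He-normal initialization (suits the ReLU that follows).
    Forward extracts strided patches into an im2col matrix and performs
    a single matmul; backward scatters the column gradient back with
    one slice-add per kernel tap.
    """

    def __init__(self, n_kernels: int, kernel_size: int, stride: int = 1,
                 padding: str = "valid") -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def build(self, input_shape, rng):
        h, w, c = input_shape
        k, s = self.kernel_size, self.stride
        if self.padding == "same":
            # pad so out = ceil(in / stride); excess goes bottom/right
            out_h = -(-h // s)
            out_w = -(-w // s)
            pad_h = max((out_h - 1) * s + k - h, 0)
            pad_w = max((out_w - 1) * s + k - w, 0)
            self._pad = (pad_h // 2, pad_h - pad_h // 2, pad_w // 2, pad_w - pad_w // 2)
            h, w = h + pad_h, w + pad_w
        else:
            self._pad = (0, 0, 0, 0)
        if k > h or k > w:
            raise ValueError(f"kernel {k} larger than input {h}x{w}")
        self.in_channels = c
        fan_in = k * k * c
        self.params = [
            (rng.standard_normal((fan_in, self.n_kernels)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            ),
            np.zeros(self.n_kernels, dtype=np.float32),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.out_h = (h - k) // s + 1
        self.out_w = (w - k) // s + 1
        return (self.out_h, self.out_w, self.n_kernels)

    def forward(self, x, training, rng):
        k, s = self.kernel_size, self.stride
        pt, pb, pl, pr = self._pad
        if any(self._pad):
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n = x.shape[0]
        # (N, oh, ow, C, k, k) strided view, then flattened patch matrix
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        cols = np.ascontiguousarray(win).reshape(n * self.out_h * self.out_w, -1)
        # weight rows are ordered (C, kh, kw) to match the window layout
        out = cols @ self.params[0] + self.params[1]
        if training:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, self.out_h, self.out_w, self.n_kernels)

    def backward(self, dout):
        k, s = self.kernel_size, self.stride
        n, oh, ow, f = dout.shape
        dmat = dout.reshape(n * oh * ow, f)
        self.grads[0][...] = self._cols.T @ dmat
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = dmat @ self.params[0].T
        dcols = dcols.reshape(n, oh, ow, self.in_channels, k, k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcols[:, :, :, :, i, j]
        del self._cols
        pt, pb, pl, pr = self._pad
        if any(self._pad):
            dx = dx[:, pt : dx.shape[1] - pb, pl : dx.shape[2] - pr, :]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling (pool size = stride); trailing rows
    and columns that do not fill a window are cropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def build(self, input_shape, rng):
        h, w, c = input_shape
        self.out_h, self.out_w = h // self.pool, w // self.pool
        if self.out_h == 0 or self.out_w == 0:
            raise ValueError(f"input {h}x{w} smaller than pool {self.pool}")
        return (self.out_h, self.out_w, c)

    def forward(self, x, training, rng):
        p = self.pool
        xc = x[:, : self.out_h * p, : self.out_w * p, :]
        win = xc.reshape(x.shape[0], self.out_h, p, self.out_w, p, x.shape[3])
        out = win.max(axis=(2, 4))
        if training:
            self._win = win
            self._out = out
            self._x_shape = x.shape
        return out

    def backward(self, dout):
        p = self.pool
        mask = self._win == self._out[:, :, None, :, None, :]
        # split gradient among ties so the total is conserved
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, : self.out_h * p, : self.out_w * p, :] = g.reshape(
            dout.shape[0], self.out_h * p, self.out_w * p, dout.shape[3]
        )
        del self._win, self._out
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float = 0.2) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._in = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training, rng):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dout):
        return dout.reshape((self._n,) + self._in)


class Dense(Layer):
    """Fully connected layer, He-normal initialized."""

    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        self.params = [
            (rng.standard_normal((fan_in, self.units)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            ),
            np.zeros(self.units, dtype=np.float32),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]
        return (self.units,)

    def forward(self, x, training, rng):
        if training:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.params[0].T
        del self._x
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class Softmax(Layer):
    """Softmax over the last axis (inference head; during training the
    loss fuses softmax with cross-entropy for stability)."""

    def forward(self, x, training, rng):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, dout):  # pragma: no cover - training bypasses this head
        raise RuntimeError("Softmax head is inference-only; train on logits")


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) vs one-hot targets, with
    the gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.shape[0]
    loss = float(-(onehot * logp).sum() / n)
    grad = ((np.exp(logp) - onehot) / n).astype(np.float32)
    return loss, grad
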