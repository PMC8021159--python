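"""Minimal NumPy building blocks for the convolutional segmenter.

Layers operate on (batch, height, width, channels) float32 tensors and
implement explicit forward/backward passes.  Convolutions use the
im2col-to-matmul formulation so the heavy lifting lands in BLAS; "same"
spatial padding is zero padding with any odd remainder on the
bottom/right (the convention for even kernels).
"""

from __future__ import annotations

import numpy as np


def _same_pad(kernel: int) -> tuple[int, int]:
    total = kernel - 1
    before = total // 2
    return before, total - before


def im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k, k, C) patches under same padding."""
    n, h, w, c = x.shape
    pt, pb = _same_pad(kernel)
    pl, pr = _same_pad(kernel)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    cols = np.empty((n, h, w, kernel, kernel, c), dtype=x.dtype)
    for i in range(kernel):
        for j in range(kernel):
            cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
    return cols


def col2im(dcols: np.ndarray, x_shape: tuple, kernel: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back."""
    n, h, w, c = x_shape
    pt, pb = _same_pad(kernel)
    pl, pr = _same_pad(kernel)
    dxp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=dcols.dtype)
    for i in range(kernel):
        for j in range(kernel):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
    return dxp[:, pt : pt + h, pl : pl + w, :]


class Conv2D:
    """Same-padded biased convolution with optional fused ReLU.

    Weights use He-normal initialization (appropriate for ReLU layers);
    the trainable parameter count is (k*k*in_ch + 1) * out_ch.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        self.relu = relu
        fan_in = kernel * kernel * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, (fan_in, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        n, h, w, _ = x.shape
        cols = im2col(x, self.kernel).reshape(n * h * w, -1)
        self._cols = cols
        out = (cols @ self.W + self.b).reshape(n, h, w, self.out_ch)
        if self.relu:
            self._act_mask = out > 0
            out = np.where(self._act_mask, out, 0.0)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = np.where(self._act_mask, grad, 0.0)
        n, h, w, _ = self._x_shape
        gmat = grad.reshape(n * h * w, self.out_ch)
        self.dW = self._cols.T @ gmat
        self.db = gmat.sum(axis=0)
        dcols = (gmat @ self.W.T).reshape(
            n, h, w, self.kernel, self.kernel, self.in_ch
        )
        self._cols = None
        return col2im(dcols, self._x_shape, self.kernel)


class MaxPool2x2:
    """2x2, stride-2 max pooling; gradient routes to the first maximum."""

    n_params = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        patches = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._argmax = patches.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(
            patches, self._argmax[..., None], axis=-1
        )[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        slots = np.zeros(grad.shape + (4,), dtype=grad.dtype)
        np.put_along_axis(slots, self._argmax[..., None], grad[..., None], axis=-1)
        return (
            slots.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class UpSample2x2:
    """Non-learned nearest-neighbour 2x upsampling."""

    n_params = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h2, w2, c = grad.shape
        return grad.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Dropout:
    """Inverted dropout: active during training only, identity at inference."""

    n_params = 0

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient wrt z.

    For y in {0,1}: loss = softplus(z) - y*z, evaluated stably; the
    gradient of the mean is (sigmoid(z) - y) / n.
    """
    z64 = z.astype(np.float64)
    softplus = np.logaddexp(0.0, z64)
    loss = float(np.mean(softplus - y * z64))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad


class Adam:
    """Adam optimizer over a fixed list of (param, grad) slots."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if hasattr(l, "params_and_grads")]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [
            np.zeros_like(p) for layer in self.layers
            for p, _ in layer.params_and_grads()
        ]
        self.v = [np.zeros_like(mm) for mm in self.m]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        i = 0
        for layer in self.layers:
            for p, g in layer.params_and_grads():
                m = self.m[i]
                v = self.v[i]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * np.square(g)
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                i += 1
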