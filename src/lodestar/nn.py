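"""Minimal CPU neural-network engine: conv layers, ReLU, max-pool, Adam.

Sized for the small fully-convolutional networks this package trains (a dozen
3x3 conv layers of 32 channels), everything is expressed as im2col + GEMM so
that single-core BLAS does the heavy lifting.  Arrays are channels-last
``(B, H, W, C)`` float32.  Every layer caches what its backward pass needs;
gradients are accumulated into ``.grads`` aligned with ``.params``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Sequential", "Adam"]

DTYPE = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B,H,W,C) -> (B*H*W, 9C) patches of a circularly padded 3x3 neighbourhood.

    Periodic padding keeps the network free of absolute-position cues: a
    zero-padded border is a landmark the receptive field can exploit to
    encode positions relative to the canvas instead of the object.
    """
    b, h, w, c = x.shape
    xp = np.empty((b, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    xp[:, 0, 1:-1, :] = x[:, -1]
    xp[:, -1, 1:-1, :] = x[:, 0]
    xp[:, :, 0, :] = xp[:, :, -2, :]
    xp[:, :, -1, :] = xp[:, :, 1, :]
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (b, h, w, 3, 3, c), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(b * h * w, 9 * c)


class Conv2d:
    """Zero-padded 'same' convolution, kernel 3x3 or 1x1, bias included.

    Weights are He-uniform initialized from the supplied generator so two
    builds from the same seed are bit-identical.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        fan_in = kernel * kernel * c_in
        bound = np.sqrt(6.0 / fan_in)
        self.weight = rng.uniform(-bound, bound, size=(kernel * kernel * c_in, c_out)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        if self.kernel == 1:
            cols = x.reshape(b * h * w, c)
        else:
            cols = _im2col3(x)
        out = cols @ self.weight + self.bias
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(b, h, w, -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, in_shape = self._cache
        b, h, w, c = in_shape
        g = gout.reshape(-1, gout.shape[-1])
        self.grads[0] += cols.T @ g
        self.grads[1] += g.sum(axis=0)
        if self.kernel == 1:
            return (g @ self.weight.T).reshape(in_shape)
        # input gradient = circularly padded correlation with the spatially
        # flipped, channel-transposed kernel (the adjoint of a periodic
        # convolution is a periodic correlation) — one more im2col GEMM
        c_out = self.weight.shape[1]
        wf = self.weight.reshape(3, 3, c, c_out)[::-1, ::-1].transpose(0, 1, 3, 2)
        gx = _im2col3(gout.astype(DTYPE, copy=False)) @ wf.reshape(9 * c_out, c)
        return gx.reshape(in_shape)

    def param_count(self) -> int:
        return self.weight.size + self.bias.size


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask

    def param_count(self) -> int:
        return 0


class MaxPool2:
    """2x2 max pooling, stride 2.  Ties share the gradient equally."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("input dimensions must be divisible by 2")
        r = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        if train:
            self._cache = (r, out)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        r, out = self._cache
        mask = (r == out[:, :, None, :, None, :]).astype(DTYPE)
        mask /= mask.sum(axis=(2, 4), keepdims=True)
        g = mask * gout[:, :, None, :, None, :]
        b, h2, _, w2, _, c = g.shape
        return g.reshape(b, h2 * 2, w2 * 2, c)

    def param_count(self) -> int:
        return 0


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.asarray(gout, dtype=DTYPE)
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)

    def state_arrays(self) -> list[np.ndarray]:
        return self.params


class Adam:
    """Adam with the standard bias correction (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
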