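"""Minimal CPU layer kit with explicit forward/backward passes.

The segmentation network used here is deliberately small (a few tens of
thousands of parameters, patches of at most a few hundred pixels per side),
so the layers are implemented directly on NumPy: every layer caches what its
backward pass needs during ``forward`` and ``backward`` returns the gradient
with respect to its input while accumulating parameter gradients in place.
Convolutions use im2col/col2im, bilinear resampling is expressed through
per-axis interpolation matrices so that its adjoint is exact.

Arrays are channel-first ``(N, C, H, W)`` float32 throughout.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "Dense",
    "SELU",
    "AlphaDropout",
    "BilinearUpsample",
    "Adam",
    "softmax",
    "softmax_backward",
]

# Self-normalizing ELU constants.
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772
# Negative saturation value dropped units are set to in Alpha-Dropout.
ALPHA_PRIME = -SELU_LAMBDA * SELU_ALPHA


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, grad_p: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities and the gradient w.r.t. them."""
    inner = (p * grad_p).sum(axis=axis, keepdims=True)
    return p * (grad_p - inner)


class Conv2d:
    """2-D convolution (cross-correlation) with optional stride and zero padding.

    Weights use LeCun-normal initialization (std = 1/sqrt(fan_in)), the
    convention matching self-normalizing SELU networks.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        std = 1.0 / math.sqrt(cin * k * k)
        self.w = rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        self._xshape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = x.shape
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
        self._cols = cols
        y = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, cout, ho, wo = g.shape
        _, cin, h, w = self._xshape
        gmat = g.transpose(0, 2, 3, 1)
        self.gw += np.tensordot(gmat, self._cols, axes=([0, 1, 2], [0, 1, 2])).reshape(
            self.w.shape
        )
        self.gb += gmat.sum(axis=(0, 1, 2))
        dcols = gmat @ self.w.reshape(cout, -1)
        dcols = dcols.reshape(n, ho, wo, cin, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Dense:
    """Affine layer acting on (N, F) inputs."""

    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = 1.0 / math.sqrt(fin)
        self.w = rng.normal(0.0, std, (fin, fout)).astype(np.float32)
        self.b = np.zeros(fout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.w.T


class SELU:
    def __init__(self) -> None:
        self._deriv: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos = x > 0
        y = SELU_LAMBDA * np.where(pos, x, SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))
        self._deriv = np.where(
            pos, SELU_LAMBDA, SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(x, 0.0))
        ).astype(np.float32)
        return y.astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._deriv


class AlphaDropout:
    """Dropout variant that preserves the self-normalizing property of SELU.

    Dropped activations are set to the SELU negative saturation value and the
    result is affinely corrected so mean and variance are retained.  With
    ``rng=None`` (deterministic inference) the layer is the identity.
    """

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        q = 1.0 - rate
        if rate > 0.0:
            self.a = (q + ALPHA_PRIME**2 * rate * q) ** -0.5
            self.b = -self.a * rate * ALPHA_PRIME
        else:  # identity
            self.a, self.b = 1.0, 0.0
        self._scale: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._scale = 1.0
            return x
        keep = rng.random(x.shape) >= self.rate
        y = self.a * np.where(keep, x, ALPHA_PRIME) + self.b
        self._scale = (self.a * keep).astype(np.float32)
        return y.astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._scale


@lru_cache(maxsize=64)
def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel-center convention)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        s = (i + 0.5) * scale - 0.5
        s0 = math.floor(s)
        f = s - s0
        a[i, min(max(s0, 0), n_in - 1)] += 1.0 - f
        a[i, min(max(s0 + 1, 0), n_in - 1)] += f
    return a


class BilinearUpsample:
    """Bilinear resampling to a fixed output size, with an exact adjoint."""

    def __init__(self, out_hw: tuple[int, int]) -> None:
        self.out_hw = out_hw
        self._in_hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        self._in_hw = (h, w)
        if (h, w) == self.out_hw:
            return x
        ar = _interp_matrix(self.out_hw[0], h)
        ac = _interp_matrix(self.out_hw[1], w)
        return np.einsum("Hh,nchw,Ww->ncHW", ar, x, ac, optimize=True)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._in_hw
        if (h, w) == self.out_hw:
            return g
        ar = _interp_matrix(self.out_hw[0], h)
        ac = _interp_matrix(self.out_hw[1], w)
        return np.einsum("Hh,ncHW,Ww->nchw", ar, g, ac, optimize=True)


class Adam:
    """Adam with (coupled) L2 weight decay added to the raw gradient."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 5e-4,
        weight_decay: float = 1e-6,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (w, g) in enumerate(self.params):
            grad = g + self.wd * w
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * grad * grad
            w -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
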