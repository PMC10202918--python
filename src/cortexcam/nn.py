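"""Minimal explicit-layer neural network stack on numpy.

The classifier and the relevance analyses both need direct access to every
layer's weights, activations and backward pass (layer-wise relevance
propagation rewrites the backward rule per layer; guided backpropagation
modifies the ReLU gate), so the network is built from small explicit layer
objects rather than an opaque graph.  Convolutions are stride-1,
same-padding, realized as im2col + BLAS matmul in float32; max pooling
uses non-overlapping kernels with first-occurrence tie-breaking.

Layout is channels-last: 2d inputs are (N, H, W, C), 3d inputs are
(N, H, W, D, C) with D the depth/time axis.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit

__all__ = [
    "Layer",
    "Conv",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "Flatten",
    "Dense",
    "Sequential",
    "bce_with_logits",
    "kaiming_normal",
]


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: forward caches whatever backward needs."""

    trainable = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; empty for stateless layers."""
        return []

    def n_params(self) -> int:
        return sum(int(np.prod(v.shape)) for _, v, _ in self.params())


def _im2col(x: np.ndarray, k: int, ndim: int) -> np.ndarray:
    """Patches of a same-padded (N, *spatial, C) array.

    Returns (N * prod(spatial), k**ndim * C) with patch axes ordered
    (k1, ..., kd, C), matching the flattened weight layout.  Built by one
    block copy per kernel offset — far more cache-friendly than gathering
    through a strided window view.
    """
    pad = k // 2
    pad_width = [(0, 0)] + [(pad, pad)] * ndim + [(0, 0)]
    xp = np.pad(x, pad_width)
    spatial = x.shape[1 : 1 + ndim]
    c = x.shape[-1]
    n_k = k**ndim
    cols = np.empty(x.shape[:-1] + (n_k, c), dtype=x.dtype)
    for idx, offs in enumerate(itertools.product(range(k), repeat=ndim)):
        sl = (
            (slice(None),)
            + tuple(slice(o, o + s) for o, s in zip(offs, spatial))
            + (slice(None),)
        )
        cols[..., idx, :] = xp[sl]
    n_pos = int(np.prod(x.shape[: 1 + ndim]))
    return cols.reshape(n_pos, n_k * c)


class Conv(Layer):
    """Stride-1 same-padding convolution for 2 or 3 spatial dims.

    Weight is stored flattened as (k**ndim * in_ch, out_ch) with C-order
    (k1, ..., kd, in_ch); ``weight_nd`` exposes the unflattened view.
    """

    def __init__(self, ndim: int, in_ch: int, out_ch: int, kernel: int = 3, *,
                 rng: np.random.Generator):
        if ndim not in (2, 3):
            raise ValueError("Conv supports 2 or 3 spatial dims")
        self.ndim = ndim
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        fan_in = (kernel**ndim) * in_ch
        self.w = kaiming_normal(rng, (fan_in, out_ch), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def weight_nd(self) -> np.ndarray:
        return self.w.reshape((self.kernel,) * self.ndim + (self.in_ch, self.out_ch))

    def conv_raw(self, x: np.ndarray, w_flat: np.ndarray, b: np.ndarray | None) -> np.ndarray:
        """Convolve x with arbitrary (flat) weights; no caching."""
        cols = _im2col(x, self.kernel, self.ndim)
        out = cols @ w_flat
        if b is not None:
            out += b
        return out.reshape(x.shape[:-1] + (w_flat.shape[1],))

    def input_grad_raw(self, gout: np.ndarray, w_flat: np.ndarray) -> np.ndarray:
        """d(loss)/d(input) given d(loss)/d(output), for arbitrary weights.

        col2im form: one GEMM against the transposed weights, then one
        scatter-add per kernel offset into the padded input buffer.
        """
        k, ndim = self.kernel, self.ndim
        pad = k // 2
        spatial = gout.shape[1 : 1 + ndim]
        dcols = gout.reshape(-1, w_flat.shape[1]) @ w_flat.T
        dcols = dcols.reshape(gout.shape[:-1] + (k**ndim, self.in_ch))
        padded_shape = (
            (gout.shape[0],)
            + tuple(s + 2 * pad for s in spatial)
            + (self.in_ch,)
        )
        dxp = np.zeros(padded_shape, dtype=dcols.dtype)
        for idx, offs in enumerate(itertools.product(range(k), repeat=ndim)):
            sl = (
                (slice(None),)
                + tuple(slice(o, o + s) for o, s in zip(offs, spatial))
                + (slice(None),)
            )
            dxp[sl] += dcols[..., idx, :]
        crop = (slice(None),) + tuple(
            slice(pad, pad + s) for s in spatial
        ) + (slice(None),)
        return dxp[crop]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._xshape = x.shape
        self._cols = _im2col(x, self.kernel, self.ndim)
        out = self._cols @ self.w + self.b
        return out.reshape(x.shape[:-1] + (self.out_ch,))

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        gflat = grad.reshape(-1, self.out_ch)
        self.dw[...] = self._cols.T @ gflat
        self.db[...] = gflat.sum(axis=0)
        return self.input_grad_raw(grad, self.w)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last)."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, train, x.shape)
        return (self.gamma * xhat + self.beta).astype(x.dtype)

    def backward(self, grad):
        xhat, inv_sd, was_train, shape = self._cache
        axes = tuple(range(grad.ndim - 1))
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        if not was_train:
            return (grad * self.gamma * inv_sd).astype(grad.dtype)
        gx = grad * self.gamma
        return (
            inv_sd
            * (gx - gx.mean(axis=axes) - xhat * (gx * xhat).mean(axis=axes))
        ).astype(grad.dtype)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class ReLU(Layer):
    """Rectifier.  With ``guided = True`` the backward pass additionally
    zeroes entries whose incoming gradient is negative (the guided-
    backpropagation gate); the default is the plain gradient rule."""

    trainable = False

    def __init__(self):
        self.guided = False
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        out = np.where(self._mask, grad, 0)
        if self.guided:
            out = np.where(grad > 0, out, 0)
        return out


class MaxPool(Layer):
    """Non-overlapping max pooling; kernel = stride, per spatial axis.

    Requires each spatial extent to be divisible by its kernel.  Ties go
    to the first (lowest-index) position, making routing deterministic.
    """

    trainable = False

    def __init__(self, kernel: tuple[int, ...]):
        self.kernel = tuple(kernel)
        self._cache = None

    def _split(self, x):
        nd = len(self.kernel)
        spatial = x.shape[1:1 + nd]
        for s, k in zip(spatial, self.kernel):
            if s % k:
                raise ValueError(
                    f"spatial extent {s} not divisible by pool kernel {k}"
                )
        out_sp = tuple(s // k for s, k in zip(spatial, self.kernel))
        shape = (x.shape[0],)
        for o, k in zip(out_sp, self.kernel):
            shape += (o, k)
        shape += (x.shape[-1],)
        xr = x.reshape(shape)
        perm = (
            [0]
            + [1 + 2 * i for i in range(nd)]
            + [1 + 2 * nd]
            + [2 + 2 * i for i in range(nd)]
        )
        xt = xr.transpose(perm)  # (N, out..., C, k1..kd)
        flat = np.ascontiguousarray(xt).reshape(xt.shape[: 2 + nd] + (-1,))
        return flat, xt.shape, perm, x.shape

    def forward(self, x, train=False):
        flat, xt_shape, perm, x_shape = self._split(x)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, xt_shape, perm, x_shape, flat.shape)
        return out

    def backward(self, grad):
        idx, xt_shape, perm, x_shape, flat_shape = self._cache
        flat = np.zeros(flat_shape, dtype=grad.dtype)
        np.put_along_axis(flat, idx[..., None], grad[..., None], axis=-1)
        xt = flat.reshape(xt_shape)
        inv = np.argsort(perm)
        return xt.transpose(inv).reshape(x_shape)


class Flatten(Layer):
    trainable = False

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, (N, in) -> (N, out)."""

    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.w = kaiming_normal(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class Sequential:
    """Plain layer chain with recordable per-layer activations."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.activations: list[np.ndarray] | None = None

    def forward(self, x, train: bool = False, record: bool = False) -> np.ndarray:
        acts = [x] if record else None
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if record:
                acts.append(x)
        self.activations = acts
        return x

    def backward(self, grad, stop_at: int = 0) -> np.ndarray:
        """Backpropagate through layers [stop_at, end); returns the gradient
        at the input of layer ``stop_at``."""
        for layer in reversed(self.layers[stop_at:]):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, v, g in layer.params():
                out.append((f"{i}.{name}", v, g))
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"{i}.{n}": v.copy() for i, l in enumerate(self.layers)
                 for n, v, _ in l.params()}
        for i, l in enumerate(self.layers):
            if isinstance(l, BatchNorm):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            for n, v, _ in l.params():
                v[...] = state[f"{i}.{n}"]
            if isinstance(l, BatchNorm):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam with decoupled-L2-style weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)  # (name, value, grad) triples
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (name, val, grad), m, v in zip(self.params, self.m, self.v):
            g = grad
            if self.weight_decay and not name.endswith((".b", ".beta")):
                g = g + self.weight_decay * val
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on raw logits; returns (mean loss, dlogits)."""
    z = logits.ravel().astype(np.float64)
    y = y.ravel().astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = expit(z)
    dz = ((p - y) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, dz
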