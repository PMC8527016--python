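"""Minimal CPU conv-net engine with explicit backpropagation.

Implements exactly the layer vocabulary the residual classifiers need:
convolutions in one or two spatial dimensions, batch normalization,
ReLU, max pooling, global average pooling and a dense head, plus the
residual block whose shortcut is scaled by a propagation coefficient W.

Layout convention is channel-last: activations are ``(N, *spatial, C)``
with spatial either ``(L,)`` or ``(H, W)``.  Convolutions are computed
as a sum of shifted matrix products (one GEMM per kernel tap), which is
memory-light and fast for the short kernels used here.  Every layer
caches what its backward pass needs; ``backward`` returns the gradient
with respect to the layer input and accumulates into ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "GlobalAvgPool",
    "Dense",
    "ResidualBlock",
    "softmax",
    "cross_entropy",
    "sgd_step",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name or 'unnamed'}, shape={self.value.shape})"


def _as_tuple(v, n):
    if np.isscalar(v):
        return (int(v),) * n
    return tuple(int(x) for x in v)


class Conv:
    """N-d convolution (cross-correlation), channel-last, no bias.

    Weight shape is ``(*kernel, C_in, C_out)``.  A bias is omitted
    because every convolution here is followed by batch normalization.
    """

    def __init__(self, in_channels, out_channels, kernel, stride, padding,
                 rng: np.random.Generator, dtype=np.float32, name=""):
        self.ndim = len(_as_tuple(kernel, 1)) if not np.isscalar(kernel) else 1
        # kernel/stride/padding may be int (1-d) or tuple
        if np.isscalar(kernel):
            kernel = (kernel,)
        self.kernel = tuple(int(k) for k in kernel)
        nd = len(self.kernel)
        self.stride = _as_tuple(stride, nd)
        self.padding = _as_tuple(padding, nd)
        fan_in = in_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(*self.kernel, in_channels, out_channels))
        self.weight = Parameter(w.astype(dtype), name=f"{name}.weight")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    @property
    def parameters(self):
        return [self.weight]

    def out_shape(self, spatial):
        return tuple((s + 2 * p - k) // st + 1 for s, k, p, st
                     in zip(spatial, self.kernel, self.padding, self.stride))

    def _pad(self, x):
        nd = len(self.kernel)
        pads = [(0, 0)] + [(p, p) for p in self.padding] + [(0, 0)]
        if all(p == 0 for p in self.padding):
            return x
        return np.pad(x, pads)

    def _cols(self, xp, out_sp):
        """im2col: (N * prod(out), prod(kernel) * C_in), kernel-major."""
        nd = len(self.kernel)
        view = sliding_window_view(xp, self.kernel,
                                   axis=tuple(range(1, nd + 1)))
        sub = tuple(slice(None, st * (o - 1) + 1, st)
                    for st, o in zip(self.stride, out_sp))
        view = view[(slice(None), *sub)]        # (N, *out, C, *k)
        view = np.moveaxis(view, nd + 1, -1)    # (N, *out, *k, C)
        return np.ascontiguousarray(view).reshape(
            -1, int(np.prod(self.kernel)) * self.in_channels)

    def forward(self, x, train=False):
        spatial = x.shape[1:-1]
        out_sp = self.out_shape(spatial)
        if any(s < 1 for s in out_sp):
            raise ValueError(
                f"input spatial shape {spatial} too small for kernel "
                f"{self.kernel} with stride {self.stride}")
        xp = self._pad(x)
        N = x.shape[0]
        wmat = self.weight.value.reshape(-1, self.out_channels)
        out = self._cols(xp, out_sp) @ wmat
        self._cache = (xp, x.shape, out_sp)
        return out.reshape(N, *out_sp, self.out_channels)

    def backward(self, dout):
        xp, x_shape, out_sp = self._cache
        nd = len(self.kernel)
        w = self.weight.value
        wmat = w.reshape(-1, self.out_channels)
        d2 = dout.reshape(-1, self.out_channels)
        cols = self._cols(xp, out_sp)
        self.weight.grad += (cols.T @ d2).reshape(w.shape)
        dcols = (d2 @ wmat.T).reshape(
            *dout.shape[:-1], *self.kernel, self.in_channels)
        dxp = np.zeros_like(xp)
        for idx in np.ndindex(*self.kernel):
            sl = tuple(slice(i, i + st * (o - 1) + 1, st)
                       for i, st, o in zip(idx, self.stride, out_sp))
            dxp[(slice(None), *sl, slice(None))] += \
                dcols[(slice(None), *([slice(None)] * nd), *idx,
                       slice(None))]
        core = tuple(slice(p, p + s) for p, s in
                     zip(self.padding, x_shape[1:-1]))
        return dxp[(slice(None), *core, slice(None))]


class BatchNorm:
    """Per-channel batch normalization (channel-last).

    Batch statistics during training; at evaluation, bias-corrected
    exponential running averages (momentum 0.1).  The bias correction
    (dividing the accumulator by 1 - (1-m)^t) makes the running
    statistics unbiased from the very first batch, which matters when
    activations have scales far from the accumulator's zero/unit
    initialization and training runs for few batches.
    """

    def __init__(self, channels, dtype=np.float32, eps=1e-5, momentum=0.1,
                 name=""):
        self.gamma = Parameter(np.ones(channels, dtype=dtype),
                               name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype),
                              name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._ema_mean = np.zeros(channels, dtype=np.float64)
        self._ema_var = np.zeros(channels, dtype=np.float64)
        self._n_updates = 0
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self._ema_mean = (1 - m) * self._ema_mean + m * mean
            self._ema_var = (1 - m) * self._ema_var + m * var
            self._n_updates += 1
            corr = 1.0 - (1.0 - m) ** self._n_updates
            self.running_mean = (self._ema_mean / corr).astype(x.dtype)
            self.running_var = (self._ema_var / corr).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, train, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, invstd, train, axes = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value * invstd
        if not train:
            return dout * g
        n = np.prod([xhat.shape[a] for a in axes])
        dxhat = dout * self.gamma.value
        dx = invstd * (dxhat
                       - dxhat.mean(axis=axes)
                       - xhat * (dxhat * xhat).mean(axis=axes))
        return dx


class ReLU:
    parameters: list = []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool:
    """Max pooling over the spatial axes (channel-last), -inf padding."""

    def __init__(self, kernel, stride, padding):
        if np.isscalar(kernel):
            kernel = (kernel,)
        self.kernel = tuple(int(k) for k in kernel)
        nd = len(self.kernel)
        self.stride = _as_tuple(stride, nd)
        self.padding = _as_tuple(padding, nd)
        self.parameters = []
        self._cache = None

    def out_shape(self, spatial):
        return tuple((s + 2 * p - k) // st + 1 for s, k, p, st
                     in zip(spatial, self.kernel, self.padding, self.stride))

    def forward(self, x, train=False):
        nd = len(self.kernel)
        spatial = x.shape[1:-1]
        out_sp = self.out_shape(spatial)
        pads = [(0, 0)] + [(p, p) for p in self.padding] + [(0, 0)]
        xp = np.pad(x, pads, constant_values=-np.inf)
        view = sliding_window_view(xp, self.kernel, axis=tuple(range(1, nd + 1)))
        # view: (N, *windows, C, *kernel); subsample by stride
        sub = tuple(slice(None, st * (o - 1) + 1, st)
                    for st, o in zip(self.stride, out_sp))
        view = view[(slice(None), *sub)]
        N = x.shape[0]
        C = x.shape[-1]
        flat = view.reshape(N, *out_sp, C, -1)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, spatial, out_sp, x.shape)
        return out

    def backward(self, dout):
        idx, spatial, out_sp, x_shape = self._cache
        nd = len(self.kernel)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        # recover per-axis kernel offsets from the flat argmax index
        offs = np.unravel_index(idx, self.kernel)
        grids = np.meshgrid(*[np.arange(o) for o in out_sp], indexing="ij")
        coords = []
        for a in range(nd):
            base = grids[a][None, ..., None] * self.stride[a]
            coords.append(base + offs[a] - self.padding[a])
        N, C = x_shape[0], x_shape[-1]
        n_idx = np.arange(N).reshape(N, *([1] * (dout.ndim - 1)))
        c_idx = np.arange(C).reshape(*([1] * (dout.ndim - 1)), C)
        n_idx, c_idx = np.broadcast_arrays(n_idx, c_idx)
        np.add.at(dx, (n_idx, *coords, c_idx), dout)
        return dx


class GlobalAvgPool:
    parameters: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = self._shape
        n_spatial = int(np.prod(shape[1:-1]))
        expand = dout.reshape(shape[0], *([1] * (len(shape) - 2)), shape[-1])
        return np.broadcast_to(expand / n_spatial, shape).astype(dout.dtype)


class Dense:
    def __init__(self, in_features, out_features, rng, dtype=np.float32,
                 name=""):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features))
        self.weight = Parameter(w.astype(dtype), name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features, dtype=dtype),
                              name=f"{name}.bias")
        self._cache = None

    @property
    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout):
        x = self._cache
        self.weight.grad += x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T


class ResidualBlock:
    """Two conv-BN-ReLU stages plus a W-scaled shortcut.

    ``y = ReLU(BN2(Conv2(ReLU(BN1(Conv1(x))))) + W * s(x))`` where the
    shortcut ``s`` is the identity when channel counts match and a
    kernel-size-1 projection otherwise.  ``coefficient`` is a scalar
    Parameter (possibly shared between blocks) or ``None`` for the
    fixed W = 1 of a plain residual network.
    """

    def __init__(self, in_channels, out_channels, ndim, rng,
                 coefficient: Parameter | None, dtype=np.float32, name=""):
        k = (3,) * ndim
        self.conv1 = Conv(in_channels, out_channels, k, 1, 1, rng, dtype,
                          name=f"{name}.conv1")
        self.bn1 = BatchNorm(out_channels, dtype, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv(out_channels, out_channels, k, 1, 1, rng, dtype,
                          name=f"{name}.conv2")
        self.bn2 = BatchNorm(out_channels, dtype, name=f"{name}.bn2")
        if in_channels != out_channels:
            self.shortcut = Conv(in_channels, out_channels, (1,) * ndim, 1, 0,
                                 rng, dtype, name=f"{name}.shortcut")
        else:
            self.shortcut = None
        self.coefficient = coefficient
        self._cache = None

    @property
    def parameters(self):
        ps = (self.conv1.parameters + self.bn1.parameters
              + self.conv2.parameters + self.bn2.parameters)
        if self.shortcut is not None:
            ps += self.shortcut.parameters
        # coefficient ownership is handled at network level (it may be shared)
        return ps

    @property
    def w_value(self) -> float:
        return 1.0 if self.coefficient is None else float(
            self.coefficient.value)

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train),
                                                train))
        f = self.bn2.forward(self.conv2.forward(h, train), train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        pre = f + self.w_value * s
        mask = pre > 0
        self._cache = (s, mask)
        return pre * mask

    def backward(self, dout):
        s, mask = self._cache
        d = dout * mask
        if self.coefficient is not None:
            self.coefficient.grad += (d * s).sum()
        ds = d * self.w_value
        df = self.bn2.backward(d)
        df = self.conv2.backward(df)
        df = self.relu1.backward(df)
        df = self.bn1.backward(df)
        dx = self.conv1.backward(df)
        if self.shortcut is None:
            dx = dx + ds
        else:
            dx = dx + self.shortcut.backward(ds)
        return dx


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(logits.dtype)


def sgd_step(parameters, lr):
    """Plain SGD update; zeroes gradients afterwards."""
    for p in parameters:
        p.value -= lr * p.grad
        p.zero_grad()
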