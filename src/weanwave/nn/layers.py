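"""Minimal CPU neural-network toolkit on numpy.

Modules cache what their backward pass needs during ``forward`` and
implement ``backward(grad_out) -> grad_in`` explicitly; there is no
dynamic autodiff graph.  This keeps the memory profile predictable and
is plenty for the fixed two-branch topology used here.  Conventions
follow the usual CNN stack: convolutions preceding a batch norm carry no
bias, batch norm holds trainable scale/shift plus non-trainable running
statistics, He-style fan-in initialization.

Gradient correctness for every layer is pinned by finite-difference
tests; do not change a backward formula without re-running those.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "Linear",
    "ReLU",
    "HardSwish",
    "HardSigmoid",
    "SiLU",
    "GlobalAvgPool2d",
    "AdaptiveAvgPool2d",
    "SqueezeExcite",
    "sigmoid",
]


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    """Base class: tracks child modules and parameters by attribute name."""

    def __setattr__(self, name, value):
        if isinstance(value, (Parameter, Module)):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, child in self.__dict__.get("_children", {}).items():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x, training: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training=training)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__setattr__("layers", list(mods))
        for i, m in enumerate(mods):
            setattr(self, f"_{i}", m)

    def forward(self, x, training: bool = False):
        for m in self.layers:
            x = m.forward(x, training=training)
        return x

    def backward(self, grad):
        for m in reversed(self.layers):
            grad = m.backward(grad)
        return grad


def _rng_for_init(shape) -> np.random.Generator:
    # init is deterministic per layer shape; callers wanting varied init
    # reinitialize via Module-level init() with an explicit rng
    return np.random.default_rng(abs(hash(shape)) % (2**31))


class Conv2d(Module):
    """2-D convolution ('same'-style padding by default) with groups
    restricted to 1 (dense) or in_channels (depthwise)."""

    def __init__(self, cin, cout, kernel, stride=1, padding=None,
                 groups=1, bias=False, rng=None):
        if groups != 1:
            if groups != cin:
                raise ValueError("groups must be 1 or in_channels")
            if cout != cin:
                raise ValueError("depthwise conv requires cout == cin")
        self.cin, self.cout, self.k = cin, cout, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * kernel * kernel
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((cout, cin // groups, kernel, kernel))
        self.weight = Parameter(w * math.sqrt(2.0 / fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self._cache = None

    def _pad(self, x):
        p = self.padding
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x, training: bool = False):
        x = np.ascontiguousarray(x, dtype=np.float64)
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s = self.k, self.stride
        if k == 1 and s == 1 and self.groups == 1:
            w = self.weight.data[:, :, 0, 0]                     # (cout, cin)
            xm = x.reshape(N, C, H * W)
            out = (w[None] @ xm).reshape(N, self.cout, H, W)
            self._cache = ("1x1", x)
        else:
            xp = self._pad(x)
            win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
            # win: (N, C, Ho, Wo, k, k)
            if self.groups == 1:
                Ho, Wo = win.shape[2], win.shape[3]
                cols = np.ascontiguousarray(
                    win.transpose(0, 2, 3, 1, 4, 5)
                ).reshape(N * Ho * Wo, C * k * k)
                wmat = self.weight.data.reshape(self.cout, C * k * k)
                out = (cols @ wmat.T).reshape(N, Ho, Wo, self.cout)
                out = out.transpose(0, 3, 1, 2)
                self._cache = ("dense", x.shape, xp.shape, cols, (Ho, Wo))
            else:  # depthwise
                out = np.einsum("nchwij,cij->nchw", win,
                                self.weight.data[:, 0], optimize=True)
                self._cache = ("dw", x.shape, xp.shape, win)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float64)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        mode = self._cache[0]
        k, s, p = self.k, self.stride, self.padding
        if mode == "1x1":
            _, x = self._cache
            N, C, H, W = x.shape
            w = self.weight.data[:, :, 0, 0]
            gm = grad.reshape(N, self.cout, H * W)
            xm = x.reshape(N, C, H * W)
            self.weight.grad[:, :, 0, 0] += (
                gm @ xm.transpose(0, 2, 1)).sum(axis=0)
            return (w.T[None] @ gm).reshape(N, C, H, W)
        if mode == "dense":
            _, xshape, xpshape, cols, (Ho, Wo) = self._cache
            N = xshape[0]
            gmat = np.ascontiguousarray(
                grad.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, self.cout)
            self.weight.grad += (gmat.T @ cols).reshape(self.weight.shape)
            dcols = (gmat @ self.weight.data.reshape(self.cout, -1)).reshape(
                N, Ho, Wo, self.cin, k, k)
            gxp = np.zeros(xpshape)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        else:  # depthwise
            _, xshape, xpshape, win = self._cache
            N, _, Ho, Wo = grad.shape
            self.weight.grad[:, 0] += np.einsum(
                "nchwij,nchw->cij", win, grad, optimize=True)
            w = self.weight.data[:, 0]
            gxp = np.zeros(xpshape)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        w[None, :, i, j, None, None] * grad
        H, W = xshape[2], xshape[3]
        return np.ascontiguousarray(gxp[:, :, p:p + H, p:p + W])


class _BatchNorm(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._axes: tuple = (0,)
        self._cache = None

    def _shape(self, v):
        raise NotImplementedError

    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=np.float64)
        if training:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = x.size // self.c
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            unbiased = var * (m / max(m - 1, 1))
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv)
        self._cache = (training, xhat, inv)
        return self._shape(self.weight.data) * xhat + self._shape(self.bias.data)

    def backward(self, grad):
        training, xhat, inv = self._cache
        grad = np.asarray(grad, dtype=np.float64)
        self.weight.grad += (grad * xhat).sum(axis=self._axes)
        self.bias.grad += grad.sum(axis=self._axes)
        gscaled = grad * self._shape(self.weight.data * inv)
        if not training:
            return gscaled
        m = grad.size // self.c
        # standard batchnorm backward through batch statistics
        sum_g = (grad * self._shape(self.weight.data)).sum(
            axis=self._axes, keepdims=True)
        sum_gx = (grad * self._shape(self.weight.data) * xhat).sum(
            axis=self._axes, keepdims=True)
        return (grad * self._shape(self.weight.data)
                - sum_g / m - xhat * sum_gx / m) * self._shape(inv)


class BatchNorm2d(_BatchNorm):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__(c, eps, momentum)
        self._axes = (0, 2, 3)

    def _shape(self, v):
        return np.asarray(v)[None, :, None, None]


class BatchNorm1d(_BatchNorm):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__(c, eps, momentum)
        self._axes = (0,)

    def _shape(self, v):
        return np.asarray(v)[None, :]


class Linear(Module):
    def __init__(self, din, dout, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(1.0 / din)
        self.weight = Parameter(rng.uniform(-bound, bound, (dout, din)))
        self.bias = Parameter(rng.uniform(-bound, bound, dout)) if bias else None
        self._x = None

    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=np.float64)
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad):
        grad = np.asarray(grad, dtype=np.float64)
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class HardSwish(Module):
    """x * relu6(x + 3) / 6."""

    def forward(self, x, training: bool = False):
        self._x = np.asarray(x, dtype=np.float64)
        return self._x * np.clip(self._x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        x = self._x
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return grad * d


class HardSigmoid(Module):
    def forward(self, x, training: bool = False):
        self._x = np.asarray(x, dtype=np.float64)
        return np.clip(self._x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        inside = (self._x > -3.0) & (self._x < 3.0)
        return np.where(inside, grad / 6.0, 0.0)


class SiLU(Module):
    """x * sigmoid(x)."""

    def forward(self, x, training: bool = False):
        self._x = np.asarray(x, dtype=np.float64)
        self._s = sigmoid(self._x)
        return self._x * self._s

    def backward(self, grad):
        s = self._s
        return grad * (s * (1.0 + self._x * (1.0 - s)))


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, training: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (H * W), self._shape).copy()


class AdaptiveAvgPool2d(Module):
    """Average-pool to a fixed (out_h, out_w) grid with the usual
    floor/ceil bin boundaries; works for any input size >= (1, 1)."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_h, self.out_w = out_hw

    @staticmethod
    def _bins(n_in, n_out):
        return [
            (int(math.floor(i * n_in / n_out)),
             int(math.ceil((i + 1) * n_in / n_out)))
            for i in range(n_out)
        ]

    def forward(self, x, training: bool = False):
        N, C, H, W = x.shape
        hb, wb = self._bins(H, self.out_h), self._bins(W, self.out_w)
        self._cache = (x.shape, hb, wb)
        out = np.empty((N, C, self.out_h, self.out_w))
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                out[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return out

    def backward(self, grad):
        shape, hb, wb = self._cache
        gx = np.zeros(shape)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                gx[:, :, h0:h1, w0:w1] += (
                    grad[:, :, i, j][:, :, None, None]
                    / ((h1 - h0) * (w1 - w0))
                )
        return gx


class SqueezeExcite(Module):
    """Channel gating: GAP -> fc (ReLU) -> fc (hard sigmoid) -> scale."""

    def __init__(self, channels, se_channels, rng=None):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, se_channels, bias=True, rng=rng)
        self.act1 = ReLU()
        self.fc2 = Linear(se_channels, channels, bias=True, rng=rng)
        self.gate = HardSigmoid()

    def forward(self, x, training: bool = False):
        self._x = x
        z = x.mean(axis=(2, 3))
        s = self.gate(self.fc2(self.act1(self.fc1(z))))
        self._s = s
        return x * s[:, :, None, None]

    def backward(self, grad):
        x, s = self._x, self._s
        gx_direct = grad * s[:, :, None, None]
        gs = (grad * x).sum(axis=(2, 3))
        gz = self.fc1.backward(self.act1.backward(
            self.fc2.backward(self.gate.backward(gs))))
        H, W = x.shape[2], x.shape[3]
        return gx_direct + gz[:, :, None, None] / (H * W)
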