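"""Neural-network layers on top of the autodiff engine.

Conventions follow the usual NCHW layout.  All parameters are float32
``Tensor`` objects; initialisation is driven by an explicit ``numpy`` RNG so
that model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "Module", "Sequential", "Conv2d", "Linear", "BatchNorm2d", "PReLU",
    "LeakyReLU", "Sigmoid", "MaxPool2d", "UpsampleBilinear2x", "concat",
]


class Module:
    """Base class: parameter discovery, train/eval mode, zero_grad."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self):
        yield self
        for v in self.__dict__.values():
            for m in _collect_modules(v):
                yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _collect_modules(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_modules(item)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, dilation=1,
                 padding=0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He initialisation
        self.weight = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, scale, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        data = x.data
        if self.training:
            mu = data.mean(axis=(0, 2, 3), keepdims=True)
            var = ((data - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.ravel())
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (data - mu) * inv_std
        gamma, beta = self.gamma, self.beta
        out_data = xhat * gamma.data.reshape(1, -1, 1, 1) + \
            beta.data.reshape(1, -1, 1, 1)
        training = self.training
        m = data.shape[0] * data.shape[2] * data.shape[3]

        def backward(g):
            dbeta = g.sum(axis=(0, 2, 3))
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            gc = gamma.data.reshape(1, -1, 1, 1)
            if training:
                # batch statistics depend on x: full BN backward
                gx = (gc * inv_std / m) * (
                    m * g
                    - dbeta.reshape(1, -1, 1, 1)
                    - xhat * dgamma.reshape(1, -1, 1, 1))
            else:
                gx = gc * inv_std * g
            return (gx.astype(data.dtype), dgamma.astype(data.dtype),
                    dbeta.astype(data.dtype))

        return Tensor._make(out_data, (x, gamma, beta), backward)


class PReLU(Module):
    """Parametric ReLU with one learnable slope per channel (init 0.25)."""

    def __init__(self, n_ch: int, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full(n_ch, init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        data = x.data
        a = self.slope.data.reshape(1, -1, 1, 1)
        factor = np.where(data > 0, data.dtype.type(1.0), a.astype(data.dtype))
        out_data = data * factor
        neg = data * (factor != 1.0)
        slope = self.slope

        def backward(g):
            gx = g * factor
            ga = (g * neg).sum(axis=(0, 2, 3))
            return gx, ga.astype(data.dtype)

        return Tensor._make(out_data, (x, slope), backward)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.relu() - self.slope * (-x).relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    """2x2 max pooling with stride 2 (the only configuration the models use)."""

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.data.shape
        if H % 2 or W % 2:
            raise ValueError(f"MaxPool2d(2) needs even spatial size, got {H}x{W}")
        xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        arg = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros((N, C, H // 2, W // 2, 4), dtype=g.dtype)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gr = gr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return (gr.reshape(N, C, H, W),)

        return Tensor._make(out_data, (x,), backward)


def _upsample_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) bilinear interpolation matrix (align_corners=False)."""
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
    i1 = np.clip(i0 + 1, 0, n - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    A = np.zeros((2 * n, n))
    A[np.arange(2 * n), i0] += 1.0 - frac
    A[np.arange(2 * n), i1] += frac
    return A


_UP_CACHE: dict[int, np.ndarray] = {}


class UpsampleBilinear2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.data.shape
        Ah = _UP_CACHE.setdefault(H, _upsample_matrix(H))
        Aw = _UP_CACHE.setdefault(W, _upsample_matrix(W)) if W != H else Ah
        out_data = np.matmul(np.matmul(Ah, x.data), Aw.T)

        def backward(g):
            return (np.matmul(np.matmul(Ah.T, g), Aw),)

        return Tensor._make(out_data, (x,), backward)
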