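"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network, the GAN and the
differentiable losses need: broadcasting arithmetic, matmul, axis reductions,
slicing, concatenation, sigmoid/log/exp/abs/relu and 2-D convolution via
im2col (with stride, dilation and zero padding).  The engine runs in
float32 and is deterministic on CPU.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # engine precision; the numpy loss paths stay float64

__all__ = ["Tensor", "concat", "conv2d", "sigmoid", "relu", "log", "exp", "tsum", "tabs"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = a / b

        def backward(g):
            return (_unbroadcast(g / b, a.shape),
                    _unbroadcast(-g * a / (b * b), b.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self.data
        out_data = a ** exponent

        def backward(g):
            return (g * exponent * a ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return self._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape
        idx_t = idx if isinstance(idx, tuple) else (idx,)
        simple = all(isinstance(i, (int, slice)) for i in idx_t)

        def backward(g):
            gx = np.zeros(shape, dtype=DTYPE)
            if simple:
                gx[idx] += g          # non-overlapping basic indexing
            else:
                np.add.at(gx, idx, g)  # fancy indexing may repeat entries
            return (gx,)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def abs(self):
        s = np.sign(self.data)

        def backward(g):
            return (g * s,)

        return self._make(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    def log(self):
        a = self.data

        def backward(g):
            return (g / a,)

        return self._make(np.log(a), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * mask,)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g
            # free intermediate storage
            node._parents = ()
            node._backward = None

    def zero_grad(self):
        self.grad = None


# -- free functions ------------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def relu(x: Tensor) -> Tensor:
    return x.relu()


def log(x: Tensor) -> Tensor:
    return x.log()


def exp(x: Tensor) -> Tensor:
    return x.exp()


def tsum(x, axis=None, keepdims=False):
    """Sum that works for both Tensor and ndarray operands."""
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tabs(x):
    """Absolute value for both Tensor and ndarray operands."""
    if isinstance(x, Tensor):
        return x.abs()
    return np.abs(x)


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


# -- convolution ----------------------------------------------------------------

_IDX_CACHE: dict = {}


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _conv_geometry(H, W, kh, kw, sh, sw, dh, dw, ph, pw):
    nh = kh + (kh - 1) * (dh - 1)
    nw = kw + (kw - 1) * (dw - 1)
    Ho = (H + 2 * ph - nh) // sh + 1
    Wo = (W + 2 * pw - nw) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"convolution input {H}x{W} smaller than effective kernel {nh}x{nw}")
    return Ho, Wo


def _conv_indices(C, H, W, kh, kw, sh, sw, dh, dw, ph, pw):
    key = (C, H, W, kh, kw, sh, sw, dh, dw, ph, pw)
    cached = _IDX_CACHE.get(key)
    if cached is not None:
        return cached
    Ho, Wo = _conv_geometry(H, W, kh, kw, sh, sw, dh, dw, ph, pw)
    Hp, Wp = H + 2 * ph, W + 2 * pw
    ii = sh * np.arange(Ho)[:, None] + dh * np.arange(kh)[None, :]      # (Ho,kh)
    jj = sw * np.arange(Wo)[:, None] + dw * np.arange(kw)[None, :]      # (Wo,kw)
    rows = np.broadcast_to(ii[:, None, :, None], (Ho, Wo, kh, kw))
    cols = np.broadcast_to(jj[None, :, None, :], (Ho, Wo, kh, kw))
    rows = rows.reshape(Ho * Wo, kh * kw)
    cols = cols.reshape(Ho * Wo, kh * kw)
    # flat gather/scatter index into (C, Hp, Wp)
    flat = (np.arange(C)[:, None, None] * (Hp * Wp)
            + rows[None] * Wp + cols[None])                              # (C,L,khkw)
    flat = np.ascontiguousarray(flat.transpose(1, 0, 2).reshape(Ho * Wo, C * kh * kw))
    out = (Ho, Wo, Hp, Wp, flat)
    _IDX_CACHE[key] = out
    return out


def _im2col(xp, flat):
    # xp: (N,C,Hp,Wp), flat: (L, C*kh*kw) indices into C*Hp*Wp
    # -> (N, L, C*kh*kw) in a single gather
    N = xp.shape[0]
    return np.take(xp.reshape(N, -1), flat, axis=1)


def _pad_nchw(x, ph, pw):
    if not (ph or pw):
        return x
    N, C, H, W = x.shape
    xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=x.dtype)
    xp[:, :, ph:ph + H, pw:pw + W] = x
    return xp


def _conv_data(xdata, wdata, bdata, sh, sw, dh, dw, ph, pw):
    """Forward convolution on raw arrays; returns (out, cols, flat, geometry)."""
    N, C, H, W = xdata.shape
    Cout = wdata.shape[0]
    kh, kw = wdata.shape[2], wdata.shape[3]
    Ho, Wo, Hp, Wp, flat = _conv_indices(C, H, W, kh, kw, sh, sw, dh, dw, ph, pw)
    cols = _im2col(_pad_nchw(xdata, ph, pw), flat)           # (N,L,CKK)
    ckk = cols.shape[2]
    out = cols.reshape(N * Ho * Wo, ckk) @ wdata.reshape(Cout, -1).T
    if bdata is not None:
        out += bdata[None, :]
    out = out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    return out, cols, flat, (Ho, Wo, Hp, Wp)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, dilation=1, padding=0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW tensors.

    ``w`` has shape (C_out, C_in, kh, kw); ``b`` shape (C_out,).  For the
    common stride-1 case the input gradient is computed as a convolution of
    the output gradient with the flipped, channel-transposed kernel (full
    padding); strided convolutions fall back to an index scatter.
    """
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cin}")
    out_data, cols_mat, flat, (Ho, Wo, Hp, Wp) = _conv_data(
        x.data, w.data, None if b is None else b.data, sh, sw, dh, dw, ph, pw)
    parents = (x, w) if b is None else (x, w, b)
    wmat = w.data.reshape(Cout, -1)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            N, Ho * Wo, Cout)
        gw = gb = gx = None
        if w.requires_grad:
            gw = (gmat.reshape(-1, Cout).T
                  @ cols_mat.reshape(-1, cols_mat.shape[2]))
            gw = gw.reshape(w.data.shape)
        if b is not None and b.requires_grad:
            gb = gmat.sum(axis=(0, 1))
        if x.requires_grad:
            if sh == sw == 1:
                # transposed-kernel route: gx = g (*) flip(w)^T, full padding
                nh = kh + (kh - 1) * (dh - 1)
                nw = kw + (kw - 1) * (dw - 1)
                wT = np.ascontiguousarray(
                    w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
                gx_full, _, _, _ = _conv_data(
                    np.ascontiguousarray(g), wT, None, 1, 1, dh, dw,
                    nh - 1 - ph, nw - 1 - pw)
                gx = gx_full
            else:
                dcols = gmat @ wmat                          # (N,L,CKK)
                flat_r = flat.ravel()
                gxp = np.empty((N, C * Hp * Wp), dtype=DTYPE)
                for n in range(N):
                    gxp[n] = np.bincount(flat_r, weights=dcols[n].ravel(),
                                         minlength=C * Hp * Wp)
                gxp = gxp.reshape(N, C, Hp, Wp)
                gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
        if b is None:
            return gx, gw
        return gx, gw, gb

    return Tensor._make(out_data, parents, backward)
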