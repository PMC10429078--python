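"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the counting network needs are provided: broadcasting
arithmetic, matmul, reductions, elementwise nonlinearities, stride-1 dilated
2-D convolution (im2col), 2x2 max pooling, bilinear upsampling and reflection
padding. All convolutions in the network have stride 1, which keeps the
backward passes simple and exact.

Tensors wrap float arrays; integer input is promoted to float32. Gradients
accumulate in ``Tensor.grad`` after ``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_float(data):
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the graph
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            return (
                (a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)),
            )

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            return (
                (a, _unbroadcast(g / b.data, a.data.shape)),
                (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
            )

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            return ((a, g * e * np.power(a.data, e - 1.0)),)

        return Tensor._make(np.power(a.data, e), (a,), bw)

    def __matmul__(self, other):
        a, b = self, other

        def bw(g):
            return ((a, g @ b.data.T), (b, a.data.T @ g))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    def __getitem__(self, key):
        a = self

        def bw(g):
            da = np.zeros_like(a.data)
            da[key] += g
            return ((a, da),)

        return Tensor._make(a.data[key], (a,), bw)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: ((a, g.reshape(old)),))

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: ((a, g.transpose(inv)),)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        shape = a.data.shape

        def bw(g):
            if axis is None:
                return ((a, np.broadcast_to(g, shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, shape).copy()),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def sigmoid(self):
        a = self
        # numerically stable logistic
        s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                     np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
        return Tensor._make(s, (a,), lambda g: ((a, g * s * (1.0 - s)),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        r = np.sqrt(a.data)
        return Tensor._make(r, (a,), lambda g: ((a, g * 0.5 / r),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through strictly interior entries."""
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: ((a, g * mask),))


# ---------------------------------------------------------------------------
# Structured operations
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution, NCHW layout, square kernel, zero padding."""
    N, C, H, W = x.data.shape
    O, Cw, k, k2 = weight.data.shape
    if Cw != C or k != k2:
        raise ValueError(f"weight shape {weight.data.shape} incompatible with input {x.data.shape}")
    d, p = int(dilation), int(padding)
    keff = d * (k - 1) + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = Hp - keff + 1, Wp - keff + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("input smaller than the effective kernel")
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))[..., ::d, ::d]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * k * k)
    wmat = weight.data.reshape(O, -1)
    out = col @ wmat.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        grads = []
        if x.requires_grad:
            dcol = gm @ wmat  # (N*Ho*Wo, C*k*k)
            dcol = dcol.reshape(N, Ho, Wo, C, k, k)
            dxp = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i * d:i * d + Ho, j * d:j * d + Wo] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
            grads.append((x, dx))
        if weight.requires_grad:
            grads.append((weight, (gm.T @ col).reshape(weight.data.shape)))
        if bias is not None and bias.requires_grad:
            grads.append((bias, gm.sum(axis=0)))
        return tuple(grads)

    return Tensor._make(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 max pooling; ties route gradient to the first max."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        db = np.zeros_like(blocks)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = db.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return ((x, dx),)

    return Tensor._make(out, (x,), bw)


def _bilinear_indices(n_in: int, factor: int):
    """Source indices/weights for 1-D bilinear resize, half-pixel convention."""
    n_out = n_in * factor
    src = (np.arange(n_out, dtype=np.float64) + 0.5) / factor - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i0 = np.minimum(i0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = (src - i0).astype(np.float32)
    return i0, i1, w


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (align_corners=False)."""
    N, C, H, W = x.data.shape
    f = int(factor)
    y0, y1, wy = _bilinear_indices(H, f)
    x0, x1, wx = _bilinear_indices(W, f)
    wyc = wy[:, None].astype(x.data.dtype)
    wxc = wx[None, :].astype(x.data.dtype)

    rows = x.data[:, :, y0, :] * (1 - wyc) + x.data[:, :, y1, :] * wyc
    out = rows[:, :, :, x0] * (1 - wxc) + rows[:, :, :, x1] * wxc

    def bw(g):
        drows = np.zeros((N, C, H * f, W), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), x0), g * (1 - wxc))
        np.add.at(drows, (slice(None), slice(None), slice(None), x1), g * wxc)
        dx = np.zeros((N, C, H, W), dtype=g.dtype)
        np.add.at(dx, (slice(None), slice(None), y0, slice(None)), drows * (1 - wyc))
        np.add.at(dx, (slice(None), slice(None), y1, slice(None)), drows * wyc)
        return ((x, dx),)

    return Tensor._make(out, (x,), bw)


def reflect_pad2d(x: Tensor, pad: int) -> Tensor:
    """Reflection padding of the two trailing (spatial) axes."""
    N, C, H, W = x.data.shape
    p = int(pad)
    out = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
    idx = np.pad(np.arange(H * W).reshape(H, W), p, mode="reflect").ravel()

    def bw(g):
        flat = np.zeros((N * C, H * W), dtype=g.dtype)
        np.add.at(flat, (np.arange(N * C)[:, None], idx[None, :]),
                  g.reshape(N * C, -1))
        return ((x, flat.reshape(N, C, H, W)),)

    return Tensor._make(out, (x,), bw)
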