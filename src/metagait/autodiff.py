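"""Reverse-mode automatic differentiation on numpy arrays.

The package trains convolutional and attention networks on a single CPU, so the
engine is deliberately small: a :class:`Tensor` wrapping an ``ndarray``, a set of
differentiable primitives (broadcast arithmetic, matmul, reductions, slicing,
concatenation, 2-D/1-D convolution, max pooling), and topological-order
backpropagation.  Gradients accumulate into ``Tensor.grad`` as plain arrays.

Every primitive's backward pass is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "no_grad",
    "is_grad_enabled",
    "conv2d",
    "conv1d",
    "maxpool2d",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g.astype(self.data.dtype, copy=False)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t._accum(g)
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                if parent._backward is None and not parent._parents:
                    parent._accum(pg)
                else:
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            )

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape)),
            )

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._make(out, (a,), lambda g: ((a, g * p * a.data ** (p - 1)),))

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * out),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * 0.5 / out),))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * (1.0 - out * out)),))

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out, (a,), lambda g: ((a, g * out * (1.0 - out)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def leaky_relu(self, slope: float = 0.01):
        a = self
        mult = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
        return Tensor._make(a.data * mult, (a,), lambda g: ((a, g * mult),))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: ((a, g * sign),))

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a2 % a.ndim for a2 in axes):
                    g = np.expand_dims(g, ax)
            return ((a, np.broadcast_to(g, a.shape).copy()),)

        return Tensor._make(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out = a.data.max(axis=axis, keepdims=True)
        # route gradient to the first maximal element along the axis
        idx = a.data.argmax(axis=axis)
        onehot = np.zeros_like(a.data)
        np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, onehot * g),)

        res = out if keepdims else out.squeeze(axis=axis)
        return Tensor._make(res, (a,), bw)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: ((a, g.reshape(a.shape)),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: ((a, g.transpose(inv)),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, key):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            return ((a, full),)

        return Tensor._make(a.data[key], (a,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the two trailing axes symmetrically."""
        a = self
        if pad == 0:
            return a
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        out = np.pad(a.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor._make(out, (a,), lambda g: ((a, g[sl]),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


# ---------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, Ho, Wo, C, kh, kw) sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (N, C, Ho*, Wo*, kh, kw); apply stride and move C after spatial
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (O,C,kh,kw), b: (O,) -> (N,O,Ho,Wo)."""
    xp = x.pad2d(pad) if pad else x
    n, c, h, ww = xp.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    ho = (h - kh) // stride + 1
    wo = (ww - kw) // stride + 1
    cols = _im2col(xp.data, kh, kw, stride)          # (N,Ho,Wo,C,kh,kw)
    cols2 = cols.reshape(n * ho * wo, c * kh * kw)
    wflat = w.data.reshape(o, -1)
    out = cols2 @ wflat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    parents = (xp, w) if b is None else (xp, w, b)

    def bw(g):
        # g: (N,O,Ho,Wo)
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        gw = (g2.T @ cols2).reshape(w.shape)
        gcols = (g2 @ wflat).reshape(n, ho, wo, c, kh, kw)
        gx = np.zeros((n, c, h, ww), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        grads = [(xp, gx), (w, gw)]
        if b is not None:
            grads.append((b, g2.sum(axis=0)))
        return tuple(grads)

    return Tensor._make(out, parents, bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D cross-correlation via conv2d. x: (N,C,L), w: (O,C,k) -> (N,O,Lo)."""
    n, c, ln = x.shape
    o, _, k = w.shape
    x4 = x.reshape(n, c, 1, ln)
    if pad:
        width = [(0, 0), (0, 0), (0, 0), (pad, pad)]
        xp = Tensor._make(
            np.pad(x4.data, width),
            (x4,),
            lambda g: ((x4, g[:, :, :, pad:-pad]),),
        )
    else:
        xp = x4
    out = conv2d(xp, w.reshape(o, c, 1, k), b, stride=stride, pad=0)
    lo = out.shape[-1]
    return out.reshape(n, o, lo)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; trailing rows/cols are cropped."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x[:, :, : ho * k, : wo * k] if (h % k or w % k) else x
    win = xc.data.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, k * k
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * k, wo * k
        )
        return ((xc, gx),)

    return Tensor._make(out, (xc,), bw)
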