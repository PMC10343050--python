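"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the tensor operations the segmentation network needs:
elementwise arithmetic with broadcasting, reductions, shape manipulation,
batched matrix products, sigmoid / leaky-ReLU / softmax nonlinearities,
3D convolution (stride 1, "same" padding) and factor-2 trilinear
upsampling.  Gradients are accumulated by a topologically ordered sweep
over the recorded computation graph.

Tensors carry float32 data by default; float64 inputs propagate, which the
test suite uses for finite-difference gradient checks.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "leaky_relu",
    "matmul",
    "sigmoid",
    "softmax",
    "upsample_trilinear2x",
]


class Tensor:
    """A NumPy array plus an optional gradient and graph bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers -------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _grad_add)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, _grad_sub)

    def __rsub__(self, other):
        return as_tensor(other, like=self) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _grad_mul)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide, _grad_div)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:

            def _bw(g, idx=idx):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

            out._backward = _bw
        return out

    # -- reductions / reshapes -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:

            def _bw(g, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (0.5 / y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if like is not None and arr.dtype != like.dtype:
        arr = arr.astype(like.dtype)
    return Tensor(arr)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a: Tensor, b, fwd, make_bw) -> Tensor:
    b = as_tensor(b, like=a)
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad, (a, b))
    if out.requires_grad:
        out._backward = make_bw(a, b, out)
    return out


def _grad_add(a, b, out):
    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))
    return _bw


def _grad_sub(a, b, out):
    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))
    return _bw


def _grad_mul(a, b, out):
    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))
    return _bw


def _grad_div(a, b, out):
    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))
    return _bw


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; batch dims of ``a`` and ``b`` must match."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))
    if out.requires_grad:

        def _bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        out._backward = _bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis),
                 any(t.requires_grad for t in ts), tuple(ts))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable: never exponentiates a large positive argument
    y = np.where(x.data >= 0,
                 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * y * (1.0 - y))
    return out


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    y = np.where(x.data >= 0, x.data, negative_slope * x.data)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        slope = np.where(x.data >= 0, 1.0, negative_slope).astype(x.dtype)
        out._backward = lambda g: x._accumulate(g * slope)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:

        def _bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

        out._backward = _bw
    return out


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3D cross-correlation, stride 1, zero "same" padding (odd kernels).

    ``x``: (N, C, D, H, W); ``weight``: (O, C, kd, kh, kw); ``bias``: (O,).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    kd, kh, kw = weight.shape[2:]
    if kd % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv3d requires odd kernel sizes for same padding")
    pads = ((0, 0), (0, 0), (kd // 2,) * 2, (kh // 2,) * 2, (kw // 2,) * 2)
    xp = np.pad(x.data, pads)
    cols = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    # cols: (N, C, D, H, W, kd, kh, kw)
    y = np.tensordot(cols, weight.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    y = np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))
    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(y, req, parents)
    if req:
        D, H, W = x.shape[2:]

        def _bw(g):
            gt = g.transpose(0, 2, 3, 4, 1)  # (N, D, H, W, O)
            if weight.requires_grad:
                gw = np.tensordot(gt, cols, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                weight._accumulate(gw)  # (O, C, kd, kh, kw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gt.sum(axis=(0, 1, 2, 3)))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            gslice = np.tensordot(gt, weight.data[:, :, i, j, k],
                                                  axes=([4], [0]))
                            gxp[:, :, i:i + D, j:j + H, k:k + W] += \
                                gslice.transpose(0, 4, 1, 2, 3)
                pd, ph, pw = kd // 2, kh // 2, kw // 2
                x._accumulate(gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])

        out._backward = _bw
    return out


def _linear_axis_weights(n_out: int, dtype) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index/weight tables for factor-2 linear upsampling along one axis."""
    n_in = n_out // 2
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0).astype(dtype)
    w1[src < 0] = 0.0
    w1[src > n_in - 1] = 0.0
    return i0, i1, w1


def upsample_trilinear2x(x: Tensor) -> Tensor:
    """Trilinear upsampling by a factor 2 per spatial axis (align_corners=False)."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    tabs = [_linear_axis_weights(2 * n, x.data.dtype) for n in (D, H, W)]

    def _up_axis(arr, axis, tab):
        i0, i1, w1 = tab
        a0 = np.take(arr, i0, axis=axis)
        a1 = np.take(arr, i1, axis=axis)
        shape = [1] * arr.ndim
        shape[axis] = len(w1)
        w = w1.reshape(shape)
        return a0 * (1 - w) + a1 * w

    y = x.data
    for ax, tab in zip((2, 3, 4), tabs):
        y = _up_axis(y, ax, tab)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:

        def _down_axis(g, axis, tab, n_in):
            i0, i1, w1 = tab
            shape = [1] * g.ndim
            shape[axis] = len(w1)
            w = w1.reshape(shape)
            out_shape = list(g.shape)
            out_shape[axis] = n_in
            acc = np.zeros(out_shape, dtype=g.dtype)
            idx0 = [slice(None)] * g.ndim
            # scatter-add the two interpolation taps
            np.add.at(acc, tuple(idx0[:axis]) + (i0,), np.moveaxis(g * (1 - w), axis, axis))
            np.add.at(acc, tuple(idx0[:axis]) + (i1,), g * w)
            return acc

        def _bw(g):
            for ax, tab, n_in in ((4, tabs[2], W), (3, tabs[1], H), (2, tabs[0], D)):
                g = _down_axis(g, ax, tab, n_in)
            x._accumulate(g)

        out._backward = _bw
    return out
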