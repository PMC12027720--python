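"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the crop autoencoder: broadcast-aware arithmetic,
batched matmul, strided conv / transposed conv via im2col-col2im, elementwise
nonlinearities, reductions, reshapes and concatenation. Gradients are
accumulated by a topological backward sweep; every op is gradient-checked in
the test suite against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # scalars follow the tensor's dtype so float32 graphs stay float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1))

        return Tensor._from_op(self.data**exponent, (self,), backward)

    # -- elementwise ----------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o**2))

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / o)

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, a=self, s=sign):
            if a.requires_grad:
                a._accum(g * s)

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, a=self, o=old):
            if a.requires_grad:
                a._accum(g.reshape(o))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g, a=self, i=inv):
            if a.requires_grad:
                a._accum(g.transpose(i))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for the conv stacks
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
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; leading batch dims of a and b must match."""

    def backward(g, ta=a, tb=b):
        if ta.requires_grad:
            ta._accum(_unbroadcast(np.matmul(g, np.swapaxes(tb.data, -1, -2)), ta.shape))
        if tb.requires_grad:
            tb._accum(_unbroadcast(np.matmul(np.swapaxes(ta.data, -1, -2), g), tb.shape))

    return Tensor._from_op(np.matmul(a.data, b.data), (a, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, ts=tensors, sp=splits, ax=axis):
        for t, piece in zip(ts, np.split(g, sp, axis=ax)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def box_mean_valid(x: Tensor, k: int) -> Tensor:
    """Mean over all k×k windows ('valid' mode) of a (B,C,H,W) tensor.

    O(N) via integral images; the adjoint is the zero-padded box mean.
    """

    def _boxsum(a: np.ndarray, kk: int) -> np.ndarray:
        # sliding-window sums over the last two axes, valid mode
        c = np.cumsum(a, axis=-2)
        c = np.concatenate([np.zeros_like(c[..., :1, :]), c], axis=-2)
        a = c[..., kk:, :] - c[..., :-kk, :]
        c = np.cumsum(a, axis=-1)
        c = np.concatenate([np.zeros_like(c[..., :, :1]), c], axis=-1)
        return c[..., :, kk:] - c[..., :, :-kk]

    scale = np.asarray(1.0 / (k * k), dtype=x.data.dtype)
    out = _boxsum(x.data, k) * scale

    def backward(g, tx=x, kk=k, sc=scale):
        if tx.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (kk - 1, kk - 1), (kk - 1, kk - 1)))
            tx._accum(_boxsum(gp, kk) * sc)

    return Tensor._from_op(out, (x,), backward)


# -- convolution ---------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(B,C,H,W) → (B, oh, ow, C·kh·kw) sliding windows at ``stride``."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # B,C,oh,ow,kh,kw
    B, C, oh, ow = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, oh, ow, C * kh * kw)


def _col2im(cols: np.ndarray, out_hw: tuple[int, int], C: int, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows back to (B,C,H,W)."""
    B, oh, ow, _ = cols.shape
    H, W = out_hw
    Hp, Wp = H + 2 * pad, W + 2 * pad
    d = cols.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += d[..., i, j]
    return out[:, :, pad : Hp - pad, pad : Wp - pad] if pad else out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); w is (Cout, Cin, kh, kw)."""
    Cout, Cin, kh, kw = w.shape
    B, C, H, W = x.shape
    assert C == Cin, f"channel mismatch {C} != {Cin}"
    cols = _im2col(x.data, kh, kw, stride, padding)  # B,oh,ow,Cin*kh*kw
    _, oh, ow, pdim = cols.shape
    wmat = w.data.reshape(Cout, pdim).T  # pdim × Cout
    out = cols.reshape(-1, pdim) @ wmat
    out = out.reshape(B, oh, ow, Cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g, tx=x, tw=w, tb=b, cols=cols, wmat=wmat):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, Cout)  # (B*oh*ow) × Cout
        if tw.requires_grad:
            dw = (cols.reshape(-1, pdim).T @ gmat).T.reshape(tw.shape)
            tw._accum(dw)
        if tb is not None and tb.requires_grad:
            tb._accum(g.sum(axis=(0, 2, 3)))
        if tx.requires_grad:
            dcols = (gmat @ wmat.T).reshape(B, oh, ow, pdim)
            tx._accum(_col2im(dcols, (H, W), Cin, kh, kw, stride, padding))

    return Tensor._from_op(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Transposed convolution; w is (Cin, Cout, kh, kw).

    Output spatial size is (H−1)·stride − 2·padding + k.
    """
    Cin, Cout, kh, kw = w.shape
    B, C, H, W = x.shape
    assert C == Cin, f"channel mismatch {C} != {Cin}"
    Ho = (H - 1) * stride - 2 * padding + kh
    Wo = (W - 1) * stride - 2 * padding + kw
    wmat = w.data.reshape(Cin, Cout * kh * kw)
    cols = (x.data.transpose(0, 2, 3, 1).reshape(-1, Cin) @ wmat).reshape(B, H, W, Cout * kh * kw)
    out = _col2im(cols, (Ho, Wo), Cout, kh, kw, stride, padding)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g, tx=x, tw=w, tb=b):
        gcols = _im2col(g, kh, kw, stride, padding)  # B,H,W,Cout*kh*kw
        gflat = gcols.reshape(-1, Cout * kh * kw)
        if tw.requires_grad:
            tw._accum((x.data.transpose(0, 2, 3, 1).reshape(-1, Cin).T @ gflat).reshape(tw.shape))
        if tb is not None and tb.requires_grad:
            tb._accum(g.sum(axis=(0, 2, 3)))
        if tx.requires_grad:
            dx = (gflat @ wmat.T).reshape(B, H, W, Cin).transpose(0, 3, 1, 2)
            tx._accum(dx)

    return Tensor._from_op(out, parents, backward)
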