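"""Minimal reverse-mode autodiff over numpy arrays.

Implements only the operations the segmentation networks and losses need:
elementwise arithmetic with broadcasting, log/exp/sigmoid/relu/clamp,
reductions, channel concatenation, 3x3/1x1 convolution, 2x2 stride-2
transposed convolution and 2x2 max pooling.  Gradients are accumulated by
topological sweep over the recorded graph.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat_channels"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._make(a.data**e, (a,), backward)

    # -- nonlinearities -------------------------------------------------------
    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip to [lo, hi]; gradient passes only through the interior."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    # -- spatial ops (NCHW) ---------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """Cross-correlation with a (C_out, C_in, k, k) kernel, stride 1."""
        x, w = self, weight
        n, cin, h, wd = x.shape
        cout, cin_w, kh, kw = w.shape
        if cin != cin_w:
            raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh, ow = h + 2 * padding - kh + 1, wd + 2 * padding - kw + 1
        # im2col: (c*kh*kw, n*oh*ow) so both passes are single GEMMs
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = np.ascontiguousarray(windows.transpose(1, 4, 5, 0, 2, 3)).reshape(
            cin * kh * kw, n * oh * ow
        )
        wmat = w.data.reshape(cout, cin * kh * kw)
        out = (wmat @ cols).reshape(cout, n, oh, ow).transpose(1, 0, 2, 3)
        if bias is not None:
            out = out + bias.data.reshape(1, cout, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, n * oh * ow)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gmat.sum(axis=1))
            if w.requires_grad:
                w._accumulate((gmat @ cols.T).reshape(w.shape))
            if x.requires_grad:
                gcols = (wmat.T @ gmat).reshape(cin, kh, kw, n, oh, ow)
                gxp = np.zeros_like(xp)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, :, di : di + oh, dj : dj + ow] += gcols[
                            :, di, dj
                        ].transpose(1, 0, 2, 3)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)

        return Tensor._make(out, parents, backward)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """2x2 transposed convolution with stride 2; kernel (C_in, C_out, 2, 2).

        Kernel and stride coincide, so output 2x2 blocks do not overlap.
        """
        x, w = self, weight
        n, cin, h, wd = x.shape
        cin_w, cout, kh, kw = w.shape
        if cin != cin_w:
            raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
        # (n, cout, h, kh, w, kw) -> (n, cout, 2h, 2w)
        out6 = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
        out = out6.reshape(n, cout, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(1, cout, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            g6 = g.reshape(n, cout, h, kh, wd, kw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accumulate(np.einsum("nohiwj,nchw->coij", g6, x.data, optimize=True))
            if x.requires_grad:
                x._accumulate(np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True))

        return Tensor._make(out, parents, backward)

    def maxpool2x2(self):
        x = self
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        argmask = blocks == out[:, :, :, None, :, None]
        # break ties toward the first max so gradient is not double-counted
        flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = flat.argmax(axis=-1)
        sel = np.zeros(flat.shape)
        np.put_along_axis(sel, first[..., None], 1.0, axis=-1)
        sel = sel.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

        def backward(g):
            if x.requires_grad:
                gb = sel * g[:, :, :, None, :, None]
                x._accumulate(gb.reshape(n, c, h, w))

        return Tensor._make(out, (x,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat_channels(tensors: Iterable[Tensor]) -> Tensor:
    """Concatenate NCHW tensors along the channel axis."""
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[1] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=1)

    def backward(g):
        start = 0
        for t, size in zip(ts, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start : start + size])
            start += size

    return Tensor._make(out_data, tuple(ts), backward)
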