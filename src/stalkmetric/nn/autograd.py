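"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an ndarray,
operations build a DAG, and :meth:`Tensor.backward` runs the reverse sweep in
topological order. Only the primitives the segmentation network needs are
provided (broadcast arithmetic, channel-wise linear maps, batched matmul,
reductions, max-pooling, softmax/log-softmax, slicing, concatenation, point
gathering and a depthwise 3x3 convolution). All gradients are exercised by
finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "gather_points", "depthwise_conv3x3",
           "channel_linear", "normalize_affine"]

#: float width of the engine; float32 keeps the memory-bound passes fast,
#: finite-difference tests switch to float64 for precision.
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (), _backward: Optional[Callable] = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(p for p in _prev if p.requires_grad)
        self._backward = _backward

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray, owned: bool = False) -> None:
        """Add ``grad`` into this node's gradient buffer.

        ``owned=True`` promises the caller just produced ``grad`` (or a view
        of an already-consumed buffer) exclusively for this node, letting the
        first accumulation adopt it without a copy.
        """
        if self.grad is None:
            if owned and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._prev))]
            seen.add(id(node))
            while stack:
                current, children = stack[-1]
                advanced = False
                for child in children:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # release the tape as we go: the closures close over this node,
            # and breaking the cycle lets refcounting free activations
            # promptly instead of waiting for the cycle collector
            node._backward = None
            node._prev = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g, owned=True)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), owned=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), owned=True)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1.0), owned=True
        )
        return out

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data, owned=True)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data, owned=True)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2), owned=True)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * mask, owned=True)
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape), owned=True)
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse), owned=True)
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _prev=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full, owned=True)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy(), owned=True)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            scale = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            scale = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / scale)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = Tensor(out_data, _prev=(self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(full, owned=True)

        out._backward = backward
        return out

    # -- fused numerical ops -------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _prev=(self,))

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot), owned=True)

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = Tensor(z - lse, _prev=(self,))

        def backward(g):
            softmax = np.exp(out.data)
            self._accumulate(g - softmax * g.sum(axis=axis, keepdims=True), owned=True)

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product along the last two axes (leading dims equal)."""
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape),
                    owned=True,
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape),
                    owned=True,
                )

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        return self.matmul(other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)], owned=True)

    out._backward = backward
    return out


def channel_linear(weight: Tensor, x: Tensor) -> Tensor:
    """Apply ``weight (C_out, C_in)`` along axis 1 of ``x (B, C_in, ...)``.

    This is the shared point-wise (1x1 convolution) map used throughout the
    network: ``y[b, o, ...] = sum_c w[o, c] * x[b, c, ...]``.
    """
    b, cin = x.shape[0], x.shape[1]
    cout = weight.shape[0]
    tail = x.shape[2:]
    xm = x.data.reshape(b, cin, -1)
    out = Tensor(np.matmul(weight.data, xm).reshape((b, cout) + tail), _prev=(weight, x))

    def backward(g):
        gm = g.reshape(b, cout, -1)
        if weight.requires_grad:
            weight._accumulate(np.einsum("bom,bcm->oc", gm, xm), owned=True)
        if x.requires_grad:
            x._accumulate(np.matmul(weight.data.T, gm).reshape(x.shape), owned=True)

    out._backward = backward
    return out


def gather_points(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather per-point features: ``x (B, C, P)`` indexed by ``idx (B, ...)``.

    Returns a tensor of shape ``(B, C, *idx.shape[1:])``; the backward pass
    scatter-adds into the source positions.
    """
    idx = np.asarray(idx)
    b, c, _ = x.shape
    gathered = np.take_along_axis(
        x.data, idx.reshape(b, 1, -1).repeat(c, axis=1), axis=2
    ).reshape((b, c) + idx.shape[1:])
    out = Tensor(gathered, _prev=(x,))

    def backward(g):
        p = x.shape[2]
        flat_g = g.reshape(b, c, -1)
        full = np.zeros_like(x.data)
        flat_idx = idx.reshape(b, -1)
        for bi in range(b):          # bincount scatter: much faster than add.at
            counts = np.bincount(flat_idx[bi], minlength=p)
            order = np.argsort(flat_idx[bi], kind="stable")
            sorted_g = flat_g[bi][:, order]
            csum = np.concatenate([[0], np.cumsum(counts[:-1])])
            summed = np.add.reduceat(
                np.concatenate([sorted_g, np.zeros((c, 1), dtype=sorted_g.dtype)], axis=1),
                np.minimum(csum, sorted_g.shape[1]), axis=1,
            )[:, :p]
            summed[:, counts == 0] = 0.0
            full[bi] = summed
        x._accumulate(full, owned=True)

    out._backward = backward
    return out


def normalize_affine(x: Tensor, gamma: Tensor, beta: Tensor, axes: Tuple[int, ...],
                     eps: float = 1e-5) -> Tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused normalize-and-affine: ``y = gamma * (x - mu) / sqrt(var + eps) + beta``.

    Statistics are computed over ``axes``; ``gamma``/``beta`` are per-channel
    (axis 1) parameters. Returns ``(y, mu, var)`` with the statistics as
    plain arrays (for running-estimate updates). One graph node instead of a
    dozen keeps the large-activation passes to a minimum.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    shape = (1, -1) + (1,) * (x.ndim - 2)
    g_r = gamma.data.reshape(shape)
    out = Tensor(g_r * xhat + beta.data.reshape(shape), _prev=(x, gamma, beta))
    reduce_param = tuple(i for i in range(x.ndim) if i != 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=reduce_param), owned=True)
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=reduce_param), owned=True)
        if x.requires_grad:
            dxhat = g * g_r
            term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * term, owned=True)

    out._backward = backward
    return out, mu, var


def depthwise_conv3x3(x: Tensor, weight: Tensor) -> Tensor:
    """Depthwise 3x3 convolution with zero padding on ``x (B, C, H, W)``.

    ``weight`` has shape ``(C, 3, 3)``; each channel is convolved with its
    own kernel, preserving the spatial shape.
    """
    b, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out_data = np.zeros_like(x.data)
    for di in range(3):
        for dj in range(3):
            out_data += weight.data[:, di, dj][None, :, None, None] * xp[:, :, di:di + h, dj:dj + w]
    out = Tensor(out_data, _prev=(x, weight))

    def backward(g):
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for di in range(3):
                for dj in range(3):
                    dw[:, di, dj] = np.einsum("bchw,bchw->c", g, xp[:, :, di:di + h, dj:dj + w])
            weight._accumulate(dw, owned=True)
        if x.requires_grad:
            gp = np.zeros_like(xp)
            for di in range(3):
                for dj in range(3):
                    gp[:, :, di:di + h, dj:dj + w] += (
                        weight.data[:, di, dj][None, :, None, None] * g
                    )
            x._accumulate(gp[:, :, 1:-1, 1:-1], owned=True)

    out._backward = backward
    return out
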