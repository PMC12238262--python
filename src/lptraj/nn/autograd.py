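"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Implements exactly the operations the trajectory models need: broadcasting
elementwise arithmetic, reductions, batched matrix products, shape
manipulation, gather-style indexing, and strided 1-D (transpose)
convolutions.  Gradients are accumulated by a topological-order sweep over
the recorded graph.  Everything is float64 end to end; the models here are
small enough that the extra precision is cheaper than chasing float32
conditioning issues.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "conv1d", "conv_transpose1d"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents
                       if id(p) not in seen and p.requires_grad]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                order.append(node)
                stack.pop()
        self._accumulate(_as_array(grad))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def gelu(self):
        # tanh approximation; smooth and cheap
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            self._accumulate(g * d)

        return Tensor(out_data, parents=(self,), backward=bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accumulate(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) == self.ndim
                                 else np.full(self.shape, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        # shift by a constant (gradient-invariant) for stability
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def bw(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        """Basic (slice/int) indexing only; no duplicated selections."""
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    def take_last(self, indices: np.ndarray):
        """Gather along the last axis with an integer index array.

        Output shape is ``self.shape[:-1] + indices.shape``; the backward
        pass scatter-adds into the gathered positions.
        """
        indices = np.asarray(indices, dtype=np.intp)
        out_data = self.data[..., indices]

        def bw(g):
            full = np.zeros_like(self.data)
            flat_idx = indices.ravel()
            g_flat = g.reshape(self.shape[:-1] + (flat_idx.size,))
            np.add.at(full.reshape(self.shape[:-1] + (self.shape[-1],)),
                      (..., flat_idx), g_flat)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    def cumsum(self, axis: int = -1):
        out_data = np.cumsum(self.data, axis=axis)

        def bw(g):
            flipped = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis),
                              axis=axis)
            self._accumulate(flipped)

        return Tensor(out_data, parents=(self,), backward=bw)

    def take_along_last(self, indices: np.ndarray):
        """Gather along the last axis with per-row integer indices
        (``indices.shape == self.shape[:-1] + (k,)``)."""
        indices = np.asarray(indices, dtype=np.intp)
        out_data = np.take_along_axis(self.data, indices, axis=-1)

        def bw(g):
            full = np.zeros_like(self.data)
            nd = self.ndim
            grid = tuple(
                np.arange(s).reshape([s if j == i else 1 for j in range(nd)])
                for i, s in enumerate(self.shape[:-1]))
            np.add.at(full, grid + (indices,), g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = _wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


# ---------------------------------------------------------------------------
# strided 1-D convolution primitives
# ---------------------------------------------------------------------------

def _conv_indices(L_pad: int, kernel: int, stride: int, dilation: int) -> np.ndarray:
    span = (kernel - 1) * dilation + 1
    L_out = (L_pad - span) // stride + 1
    if L_out <= 0:
        raise ValueError("convolution output length would be non-positive")
    starts = np.arange(L_out) * stride
    taps = np.arange(kernel) * dilation
    return starts[:, None] + taps[None, :]  # (L_out, K)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Cross-correlation of ``x`` (B, C_in, L) with ``w`` (C_out, C_in, K).

    Computed as K per-tap batched matrix products on strided views, which
    avoids materializing an im2col tensor.
    """
    x = _wrap(x)
    w = _wrap(w)
    B, C_in, L = x.shape
    C_out, C_in_w, K = w.shape
    if C_in_w != C_in:
        raise ValueError("channel mismatch in conv1d")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    span = (K - 1) * dilation + 1
    L_out = (xp.shape[-1] - span) // stride + 1
    if L_out <= 0:
        raise ValueError("convolution output length would be non-positive")

    def tap(k):  # strided view of the input window for kernel tap k
        start = k * dilation
        return xp[:, :, start:start + stride * L_out:stride]

    out_data = np.matmul(w.data[:, :, 0], tap(0))
    for k in range(1, K):
        out_data += np.matmul(w.data[:, :, k], tap(k))
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(K):
                gw[:, :, k] = np.tensordot(g, tap(k), axes=([0, 2], [0, 2]))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                start = k * dilation
                gxp[:, :, start:start + stride * L_out:stride] += \
                    np.matmul(w.data[:, :, k].T, g)
            if padding:
                gxp = gxp[:, :, padding:gxp.shape[-1] - padding]
            x._accumulate(gxp)

    return Tensor(out_data, parents=parents, backward=bw)


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 1, padding: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed convolution of ``x`` (B, C_in, L) with ``w`` (C_in, C_out, K).

    Output length is ``(L - 1) * stride - 2 * padding + K + output_padding``,
    the exact inverse of the matching strided ``conv1d`` shape rule.
    """
    x = _wrap(x)
    w = _wrap(w)
    B, C_in, L = x.shape
    C_in_w, C_out, K = w.shape
    if C_in_w != C_in:
        raise ValueError("channel mismatch in conv_transpose1d")
    L_full = (L - 1) * stride + K
    L_out = L_full - 2 * padding + output_padding
    if L_out <= 0:
        raise ValueError("transpose-convolution output length would be non-positive")

    full = np.zeros((B, C_out, L_full + output_padding))
    for k in range(K):
        full[:, :, k:k + stride * L:stride] += np.matmul(w.data[:, :, k].T, x.data)
    out_data = full[:, :, padding:padding + L_out]
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g_full = np.zeros((B, C_out, L_full + output_padding))
        g_full[:, :, padding:padding + L_out] = g

        def tap(k):
            return g_full[:, :, k:k + stride * L:stride]

        if x.requires_grad:
            gx = np.matmul(w.data[:, :, 0], tap(0))
            for k in range(1, K):
                gx += np.matmul(w.data[:, :, k], tap(k))
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(K):
                gw[:, :, k] = np.tensordot(x.data, tap(k), axes=([0, 2], [0, 2]))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))

    return Tensor(out_data, parents=parents, backward=bw)
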