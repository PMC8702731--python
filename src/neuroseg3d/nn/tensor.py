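"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

The engine exists to train modest 3D convolutional networks on a CPU. It is
deliberately small: a :class:`Tensor` wraps an ndarray and records a closure
that propagates the output gradient to its parents; :meth:`Tensor.backward`
replays the tape in reverse topological order.

Conventions
-----------
* Volumetric activations are **channels-last**: ``(N, Z, H, W, C)``. This
  keeps every convolution a plain matrix product over the channel axis,
  which is where BLAS does the heavy lifting.
* Convolution weights are stored ``(k, k, k, C_in, C_out)``; biases ``(C_out,)``.
* All parameters are float32 by default; ops preserve the dtype of their
  inputs so numerical gradient checks can run a model in float64.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "relu", "log", "exp", "power",
    "softmax", "log_softmax", "tensor_sum", "tensor_mean",
    "reshape", "transpose", "concat", "narrow",
    "conv3d", "maxpool3d", "upsample_nearest3d", "batch_norm",
]


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor_like(other, self) if isinstance(other, Tensor) else -other)

    def __rsub__(self, other):
        return add(-self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __getitem__(self, idx):
        return _slice(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor_like(x, ref: Tensor) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=ref.data.dtype))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    if not req:
        # Inference path: no tape.
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    b = _as_tensor_like(b, a)
    data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(data, (a, b), bw)


def mul(a: Tensor, b) -> Tensor:
    b = _as_tensor_like(b, a)
    data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), bw)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(data, (a,), bw)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _node(data, (a,), bw)


def log(a: Tensor, clamp: float = 1e-12) -> Tensor:
    safe = np.maximum(a.data, clamp)
    data = np.log(safe)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / safe)

    return _node(data, (a,), bw)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * data)

    return _node(data, (a,), bw)


def tensor_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shape)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _node(data, (a,), bw)


def tensor_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate(data * (g - dot))

    return _node(data, (a,), bw)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    data = x - lse

    def bw(g):
        if a.requires_grad:
            soft = np.exp(data)
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return _node(data, (a,), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _node(data, (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    data = a.data.transpose(axes)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _node(data, (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _node(data, tuple(tensors), bw)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (used for channel splits)."""
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

    return _node(data, (a,), bw)


def _slice(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

    return _node(data, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product on the trailing two axes (equal leading dims)."""
    data = np.matmul(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape))

    return _node(data, (a, b), bw)


# ---------------------------------------------------------------------------
# volumetric ops
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, 'same' zero padding for odd kernels.

    ``x``: (N, Z, H, W, C_in); ``w``: (k, k, k, C_in, C_out); ``b``: (C_out,).

    Implemented as a shift-and-matmul loop over the k^3 kernel offsets so the
    inner operation is a (voxels, C_in) @ (C_in, C_out) product.
    """
    k = w.data.shape[0]
    if w.data.shape[1] != k or w.data.shape[2] != k:
        raise ValueError(f"only cubic kernels supported, got {w.data.shape[:3]}")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd for 'same' padding")
    n, z, h, ww_, cin = x.data.shape
    if w.data.shape[3] != cin:
        raise ValueError(f"weight expects {w.data.shape[3]} input channels, got {cin}")
    cout = w.data.shape[4]
    p = k // 2
    if p:
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    else:
        xp = x.data
    out = np.zeros((n, z, h, ww_, cout), dtype=x.data.dtype)
    wd = w.data
    for dz in range(k):
        for dh in range(k):
            for dw in range(k):
                xs = xp[:, dz:dz + z, dh:dh + h, dw:dw + ww_, :]
                out += np.matmul(xs, wd[dz, dh, dw])
    if b is not None:
        out += b.data

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if x.requires_grad:
            # gather form: correlate the padded output gradient with the
            # flipped, transposed kernel (contiguous accumulation)
            gp = np.pad(g, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else g
            gx = np.zeros_like(x.data)
            for dz in range(k):
                for dh in range(k):
                    for dw in range(k):
                        gs = gp[:, dz:dz + z, dh:dh + h, dw:dw + ww_, :]
                        gx += np.matmul(gs, wd[k - 1 - dz, k - 1 - dh, k - 1 - dw].T)
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.empty_like(wd)
            g_mat = np.ascontiguousarray(g).reshape(-1, cout)
            for dz in range(k):
                for dh in range(k):
                    for dw in range(k):
                        xs = xp[:, dz:dz + z, dh:dh + h, dw:dw + ww_, :]
                        xs_mat = np.ascontiguousarray(xs).reshape(-1, cin)
                        gw[dz, dh, dw] = xs_mat.T @ g_mat
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2, 3)))

    return _node(out, parents, bw)


def maxpool3d(x: Tensor) -> Tensor:
    """2x max pooling on each spatial axis; spatial dims must be even."""
    n, z, h, w, c = x.data.shape
    if z % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d requires even spatial dims, got {(z, h, w)}")
    xr = x.data.reshape(n, z // 2, 2, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4, 6))

    def bw(g):
        if not x.requires_grad:
            return
        mask = xr == out[:, :, None, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :, None, :] / cnt)
        x._accumulate(gx.reshape(x.data.shape))

    return _node(out, (x,), bw)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling on each spatial axis."""
    n, z, h, w, c = x.data.shape
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        if x.requires_grad:
            gr = g.reshape(n, z, 2, h, 2, w, 2, c).sum(axis=(2, 4, 6))
            x._accumulate(gr)

    return _node(out, (x,), bw)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over the (N, Z, H, W) axes.

    ``running_mean``/``running_var`` are plain arrays updated in place when
    ``training`` is true.
    """
    axes = (0, 1, 2, 3)
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m = running_mean.astype(x.data.dtype)
        v = running_var.astype(x.data.dtype)
    ivar = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * ivar
    out = gamma.data * xhat + beta.data

    nred = int(np.prod([x.data.shape[a] for a in axes]))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if not x.requires_grad:
            return
        gxh = g * gamma.data
        if training:
            s1 = gxh.sum(axis=axes)
            s2 = (gxh * xhat).sum(axis=axes)
            gx = ivar / nred * (nred * gxh - s1 - xhat * s2)
        else:
            gx = gxh * ivar
        x._accumulate(gx.astype(x.data.dtype, copy=False))

    return _node(out, (x, gamma, beta), bw)
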