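"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's tensor engine: a :class:`Tensor` wraps a float64
numpy array and records the operations applied to it, so that a scalar
loss can be backpropagated through the segmentation network.  Only the
primitives the architecture actually needs are provided — elementwise
arithmetic and activations, reductions, reshaping/concatenation, 2D
padding (zero / reflect / edge), strided-dilated-grouped 2D convolution,
matrix-based separable resampling, and a circular 1D convolution over
the channel axis for channel attention.

All convolutions are cross-correlations (no kernel flip), the usual
deep-learning convention.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "power",
    "tensor_sum",
    "tensor_mean",
    "reshape",
    "concat",
    "pad2d",
    "conv2d",
    "avg_pool2d",
    "global_avg_pool",
    "resize2d",
    "circular_conv1d",
    "log_softmax",
]


class Tensor:
    """A float64 array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate ``grad`` (defaults to ones) from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}

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

        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        s = np.where(
            x.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x.data))),
            np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))),
        )
    return _make(s, (x,), lambda g: (g * s * (1.0 - s),))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return _make(e, (x,), lambda g: (g * e,))


def log(x: Tensor) -> Tensor:
    return _make(np.log(x.data), (x,), lambda g: (g / x.data,))


def power(x: Tensor, p: float) -> Tensor:
    data = x.data ** p
    return _make(data, (x,), lambda g: (g * p * x.data ** (p - 1.0),))


# ---------------------------------------------------------------------
# reductions & shape
# ---------------------------------------------------------------------

def tensor_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(a % x.data.ndim for a in axes)
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, x.data.shape).copy(),)

    return _make(data, (x,), backward)


def tensor_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tensor_sum(x, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(x: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _make(x.data.reshape(shape), (x,), lambda g: (g.reshape(x.data.shape),))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tensors, backward)


# ---------------------------------------------------------------------
# 2D padding
# ---------------------------------------------------------------------

def _pad_src_index(n: int, lo: int, hi: int, mode: str) -> np.ndarray:
    idx = np.arange(-lo, n + hi)
    if mode == "edge":
        return np.clip(idx, 0, n - 1)
    if mode == "reflect":
        if lo > n - 1 or hi > n - 1:
            raise ShapeError(
                f"reflect padding ({lo},{hi}) wider than input extent {n}"
            )
        if n == 1:
            return np.zeros_like(idx)
        m = np.mod(idx, 2 * (n - 1))
        return np.where(m >= n, 2 * (n - 1) - m, m)
    raise ConfigurationError(f"unknown padding mode {mode!r}")


def pad2d(x: Tensor, pad_h: tuple, pad_w: tuple, mode: str = "zeros") -> Tensor:
    """Pad the two trailing axes of an NCHW tensor."""
    (pt, pb), (pl, pr) = pad_h, pad_w
    if min(pt, pb, pl, pr) < 0:
        raise ConfigurationError("negative padding")
    if pt == pb == pl == pr == 0:
        return x
    N, C, H, W = x.data.shape
    if mode == "zeros":
        data = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))

        def backward(g):
            return (g[:, :, pt:pt + H, pl:pl + W],)

        return _make(data, (x,), backward)

    src_h = _pad_src_index(H, pt, pb, mode)
    src_w = _pad_src_index(W, pl, pr, mode)
    data = x.data[:, :, src_h[:, None], src_w[None, :]]
    flat_idx = (src_h[:, None] * W + src_w[None, :]).ravel()

    def backward(g):
        # C-order zeros so the reshape below is a writable view
        gx = np.zeros(x.data.shape, dtype=np.float64)
        target = gx.reshape(N * C, H * W).T
        np.add.at(target, flat_idx, np.ascontiguousarray(g).reshape(N * C, -1).T)
        return (gx,)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------

def _conv2d_nopad(x: Tensor, w: Tensor, b, stride: int, dilation: int,
                  groups: int) -> Tensor:
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    G = groups
    if C != Cg * G:
        raise ShapeError(
            f"input has {C} channels but kernel expects {Cg}×{G} (groups)"
        )
    if O % G != 0:
        raise ShapeError(f"out_channels {O} not divisible by groups {G}")
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    if H < eh or W < ew:
        raise ShapeError(
            f"effective kernel {eh}×{ew} exceeds (padded) input {H}×{W}"
        )
    Ho = (H - eh) // stride + 1
    Wo = (W - ew) // stride + 1
    ih = stride * np.arange(Ho)[:, None] + dilation * np.arange(kh)[None, :]
    iw = stride * np.arange(Wo)[:, None] + dilation * np.arange(kw)[None, :]
    patches = x.data[:, :, ih[:, None, :, None], iw[None, :, None, :]]
    Og = O // G
    pm = (
        patches.reshape(N, G, Cg, Ho, Wo, kh, kw)
        .transpose(1, 0, 3, 4, 2, 5, 6)
        .reshape(G, N * Ho * Wo, Cg * kh * kw)
    )
    wm = w.data.reshape(G, Og, Cg * kh * kw).transpose(0, 2, 1)
    out = pm @ wm  # (G, N*Ho*Wo, Og)
    out = np.ascontiguousarray(
        out.reshape(G, N, Ho, Wo, Og)
        .transpose(1, 0, 4, 2, 3)
        .reshape(N, O, Ho, Wo)
    )
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def backward(g):
        gm = (
            g.reshape(N, G, Og, Ho, Wo)
            .transpose(1, 0, 3, 4, 2)
            .reshape(G, N * Ho * Wo, Og)
        )
        gw = (pm.transpose(0, 2, 1) @ gm).transpose(0, 2, 1).reshape(O, Cg, kh, kw)
        gpm = gm @ wm.transpose(0, 2, 1)
        gpatches = (
            gpm.reshape(G, N, Ho, Wo, Cg, kh, kw)
            .transpose(1, 0, 4, 2, 3, 5, 6)
            .reshape(N, C, Ho, Wo, kh, kw)
        )
        gx = np.zeros_like(x.data)
        for u in range(kh):
            for v in range(kw):
                gx[
                    :, :,
                    dilation * u: dilation * u + stride * Ho: stride,
                    dilation * v: dilation * v + stride * Wo: stride,
                ] += gpatches[:, :, :, :, u, v]
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    if b is None:
        return _make(out, parents, lambda g: backward(g)[:2])
    return _make(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b=None, stride: int = 1, dilation: int = 1,
           groups: int = 1, padding=None, padding_mode: str = "zeros") -> Tensor:
    """2D cross-correlation on an NCHW tensor.

    ``padding`` of ``None`` means "same" padding (only valid for stride 1
    with odd effective kernel extents); an int or ``(ph, pw)`` pads both
    sides of each axis by that amount.
    """
    if stride < 1 or dilation < 1:
        raise ConfigurationError("stride and dilation must be positive")
    _, _, kh, kw = w.data.shape
    if padding is None or (isinstance(padding, str) and padding == "same"):
        ph = dilation * (kh - 1) // 2
        pw = dilation * (kw - 1) // 2
    elif isinstance(padding, int):
        ph = pw = padding
    else:
        ph, pw = padding
    xp = pad2d(x, (ph, ph), (pw, pw), mode=padding_mode)
    return _conv2d_nopad(xp, w, b, stride, dilation, groups)


def avg_pool2d(x: Tensor, kernel_size: int, stride: int = 1,
               same: bool = True) -> Tensor:
    """Average pooling as a constant-weight depthwise convolution.

    With ``same=True`` the input is zero padded so spatial size is
    preserved (for stride 1); border averages therefore include the
    zero padding in their denominator.
    """
    C = x.data.shape[1]
    k = kernel_size
    w = Tensor(np.full((C, 1, k, k), 1.0 / (k * k)))
    padding = (k - 1) // 2 if same else 0
    return conv2d(x, w, None, stride=stride, groups=C, padding=padding)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keeping them as singletons (N,C,1,1)."""
    return tensor_mean(x, axis=(2, 3), keepdims=True)


# ---------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------

def resize2d(x: Tensor, row_weights: np.ndarray, col_weights: np.ndarray) -> Tensor:
    """Separable linear resampling: ``out = R @ x @ C^T`` per image/channel.

    ``row_weights`` has shape (H_out, H_in) and ``col_weights``
    (W_out, W_in); both are plain arrays (not differentiated).
    """
    R = np.asarray(row_weights, dtype=np.float64)
    Cw = np.asarray(col_weights, dtype=np.float64)
    data = np.einsum("nchw,ph,qw->ncpq", x.data, R, Cw, optimize=True)

    def backward(g):
        return (np.einsum("ncpq,ph,qw->nchw", g, R, Cw, optimize=True),)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------
# channel-axis circular 1D convolution (local cross-channel interaction)
# ---------------------------------------------------------------------

def circular_conv1d(x: Tensor, w: Tensor) -> Tensor:
    """1D cross-correlation over axis 1 of an (N, C) tensor with circular
    extension; the kernel (odd length k) is centred, so
    ``out[n,c] = Σ_j w[j]·x[n, (c + j − k//2) mod C]``."""
    k = w.data.shape[0]
    if k % 2 != 1:
        raise ConfigurationError("circular_conv1d kernel length must be odd")
    C = x.data.shape[1]
    if C < k:
        raise ConfigurationError(f"channel count {C} smaller than kernel {k}")
    half = k // 2
    shifted = np.stack(
        [np.roll(x.data, -(j - half), axis=1) for j in range(k)], axis=0
    )
    out = np.tensordot(w.data, shifted, axes=1)

    def backward(g):
        gx = np.zeros_like(x.data)
        for j in range(k):
            gx += w.data[j] * np.roll(g, j - half, axis=1)
        gw = np.array([(g * shifted[j]).sum() for j in range(k)])
        return (gx, gw)

    return _make(out, (x, w), backward)


# ---------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------

def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))

    def backward(g):
        return (g - np.exp(ls) * g.sum(axis=axis, keepdims=True),)

    return _make(ls, (x,), backward)
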