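"""The low-level operators the architecture is assembled from.

Four families: atrous (dilated) convolution, depthwise-separable
convolution (depthwise + pointwise), bicubic upsampling with the Keys
cubic-convolution kernel, and the reflection-padded convolution stack
with bilinear upsampling used by the auxiliary branch.

Every function accepts either a plain NCHW numpy array or an autograd
:class:`~plaquenet.autograd.Tensor` and returns the same kind, so the
same code path serves both the functional/test surface and the trained
network.

Conventions (fixed across the package):

* all convolutions are cross-correlations (no kernel flip);
* "same" padding preserves spatial size; atrous convolutions zero pad
  by ``rate·(k−1)/2`` per axis;
* resampling maps destination to source coordinates with the
  half-pixel-centre (align-corners=false) rule ``src = (dst+0.5)/scale − 0.5``;
* out-of-range interpolation taps clamp to the edge sample.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "cubic_kernel",
    "cubic_interp_weights",
    "bilinear_corner_weights",
    "resample_matrix",
    "avg2x2_matrix",
    "atrous_conv",
    "depthwise_conv",
    "pointwise_conv",
    "depthwise_separable_conv",
    "bicubic_upsample",
    "reflect_conv_stack",
    "bilinear_reflect_upsample",
]

KEYS_A = -0.5  # sharpness of the Keys cubic-convolution kernel


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 4:
        raise ShapeError(f"expected NCHW feature map, got shape {arr.shape}")
    return Tensor(arr), False


def _unwrap(t: Tensor, was_tensor: bool):
    return t if was_tensor else t.data


def _kernel_tensor(k, shape_hint: str):
    if isinstance(k, Tensor):
        return k
    arr = np.asarray(k, dtype=np.float64)
    if arr.ndim != 4:
        raise ShapeError(
            f"{shape_hint} kernel must be 4D (out, in/groups, kH, kW), got {arr.shape}"
        )
    return Tensor(arr)


def _bias_tensor(b):
    if b is None or isinstance(b, Tensor):
        return b
    return Tensor(np.asarray(b, dtype=np.float64))


# ---------------------------------------------------------------------
# interpolation kernels
# ---------------------------------------------------------------------

def cubic_kernel(t, a: float = KEYS_A):
    """Keys cubic-convolution kernel δ(t): an interpolating kernel with
    δ(0)=1, δ(±1)=δ(±2)=0 and 4-sample support per axis."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near] ** 3 - (a + 3) * t[near] ** 2 + 1
    out[far] = a * t[far] ** 3 - 5 * a * t[far] ** 2 + 8 * a * t[far] - 4 * a
    return out


def cubic_interp_weights(frac, a: float = KEYS_A) -> np.ndarray:
    """The four per-axis bicubic weights δ(frac − i), i ∈ {−1,0,1,2};
    they sum to 1 for any fractional offset (partition of unity)."""
    frac = np.asarray(frac, dtype=np.float64)
    return np.stack([cubic_kernel(frac - i, a) for i in (-1, 0, 1, 2)], axis=-1)


def bilinear_corner_weights(alpha_x, alpha_y) -> np.ndarray:
    """The four bilinear corner weights
    (1−αx)(1−αy), αx(1−αy), (1−αx)αy, αxαy — nonnegative, summing to 1."""
    ax = np.asarray(alpha_x, dtype=np.float64)
    ay = np.asarray(alpha_y, dtype=np.float64)
    return np.stack(
        [(1 - ax) * (1 - ay), ax * (1 - ay), (1 - ax) * ay, ax * ay], axis=-1
    )


def resample_matrix(n_in: int, scale: float, kind: str = "bicubic",
                    a: float = KEYS_A, alpha=None) -> np.ndarray:
    """Dense (n_out × n_in) one-axis resampling operator.

    Destination pixel i samples source coordinate (i+0.5)/scale − 0.5;
    taps falling outside [0, n_in) clamp to the border sample.  For
    ``kind="bilinear"`` an explicit ``alpha`` array overrides the
    fractional offsets (one per output pixel).
    """
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    if n_in < 2:
        raise ShapeError("resampling requires input extent >= 2")
    n_out = int(round(n_in * scale))
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    base = np.floor(src).astype(int)
    frac = src - base
    if kind == "bicubic":
        taps, weights = (-1, 0, 1, 2), cubic_interp_weights(frac, a)
    elif kind == "bilinear":
        if alpha is not None:
            frac = np.asarray(alpha, dtype=np.float64)
            if frac.shape != (n_out,):
                raise ShapeError(
                    f"alpha must have one entry per output pixel ({n_out})"
                )
        taps, weights = (0, 1), np.stack([1 - frac, frac], axis=-1)
    else:
        raise ConfigurationError(f"unknown resampling kind {kind!r}")
    M = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    for j, tap in enumerate(taps):
        idx = np.clip(base + tap, 0, n_in - 1)
        np.add.at(M, (rows, idx), weights[:, j])
    return M


def avg2x2_matrix(n: int) -> np.ndarray:
    """One-axis operator of the stride-1 2×2 mean filter with the last
    row/column edge-replicated, so shape and constants are preserved."""
    M = np.zeros((n, n))
    rows = np.arange(n)
    np.add.at(M, (rows, rows), 0.5)
    np.add.at(M, (rows, np.minimum(rows + 1, n - 1)), 0.5)
    return M


# ---------------------------------------------------------------------
# convolution operators
# ---------------------------------------------------------------------

def atrous_conv(q, kernel, bias=None, rate: int = 1):
    """Dilated convolution: output(c,d) = Σ_{i,j} q(c+e·i, d+e·j)·k(i,j),
    with zero "same" padding of rate·(k−1)/2 per axis."""
    if int(rate) != rate or rate < 1:
        raise ConfigurationError(f"atrous rate must be a positive int, got {rate}")
    x, was = _wrap(q)
    w = _kernel_tensor(kernel, "atrous")
    out = ag.conv2d(x, w, _bias_tensor(bias), dilation=int(rate), padding="same")
    return _unwrap(out, was)


def depthwise_conv(q, kernel, bias=None):
    """Per-channel spatial convolution (no cross-channel mixing);
    kernel shape (C, 1, kH, kW), "same" zero padding."""
    x, was = _wrap(q)
    w = _kernel_tensor(kernel, "depthwise")
    C = x.data.shape[1]
    if w.data.shape[0] != C or w.data.shape[1] != 1:
        raise ShapeError(
            f"depthwise kernel {w.data.shape} does not match {C} input channels "
            "(expected (C, 1, kH, kW))"
        )
    out = ag.conv2d(x, w, _bias_tensor(bias), groups=C, padding="same")
    return _unwrap(out, was)


def pointwise_conv(q, kernel, bias=None):
    """1×1 cross-channel mixing: output_o(i,j) = Σ_v k[o,v]·Q_v(i,j)."""
    x, was = _wrap(q)
    w = kernel if isinstance(kernel, Tensor) else Tensor(np.asarray(kernel, dtype=np.float64))
    if w.data.ndim == 2:
        w = ag.reshape(w, w.data.shape + (1, 1))
    if w.data.ndim != 4 or w.data.shape[2:] != (1, 1):
        raise ConfigurationError(
            f"pointwise kernel must have 1×1 spatial extent, got {w.data.shape}"
        )
    out = ag.conv2d(x, w, _bias_tensor(bias), padding=0)
    return _unwrap(out, was)


def depthwise_separable_conv(q, depthwise_kernel, pointwise_kernel,
                             bias=None):
    """Depthwise then pointwise convolution — the factorized convolution
    with kH·kW·C + C·O parameters instead of the dense kH·kW·C·O."""
    x, was = _wrap(q)
    mid = depthwise_conv(x, depthwise_kernel)
    out = pointwise_conv(mid, pointwise_kernel, bias)
    return _unwrap(out, was)


# ---------------------------------------------------------------------
# resampling operators
# ---------------------------------------------------------------------

def bicubic_upsample(q, scale: float, a: float = KEYS_A):
    """Bicubic resampling: each output pixel is the 16-neighbour weighted
    sum Σ_{ij} Q(i,j)·δ(y−y_j)·δ(x−x_i) with edge-clamped borders."""
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    x, was = _wrap(q)
    _, _, H, W = x.data.shape
    Rm = resample_matrix(H, scale, "bicubic", a)
    Cm = resample_matrix(W, scale, "bicubic", a)
    return _unwrap(ag.resize2d(x, Rm, Cm), was)


def bicubic_resize_to(q, out_h: int, out_w: int, a: float = KEYS_A):
    """Bicubic resampling to an explicit output size."""
    x, was = _wrap(q)
    _, _, H, W = x.data.shape
    return _unwrap(
        ag.resize2d(x, resample_matrix(H, out_h / H, "bicubic", a),
                    resample_matrix(W, out_w / W, "bicubic", a)),
        was,
    )


def reflect_conv_stack(r, kernels, biases=None):
    """N stacked K×K convolutions, each reflection-padded so spatial size
    is preserved (no border attenuation, unlike zero padding)."""
    x, was = _wrap(r)
    kernels = list(kernels)
    if not kernels:
        raise ConfigurationError("reflect_conv_stack needs at least one kernel")
    if biases is None:
        biases = [None] * len(kernels)
    for w, b in zip(kernels, biases):
        wt = _kernel_tensor(w, "reflect-stack")
        x = ag.conv2d(x, wt, _bias_tensor(b), padding="same",
                      padding_mode="reflect")
    return _unwrap(x, was)


def bilinear_reflect_upsample(r, scale: float, alpha_x=None, alpha_y=None,
                              apply_avg: bool = True):
    """Bilinear 4-neighbour blend followed by the F_Avg smoothing pass.

    The blend of output pixel (with per-axis offsets αx, αy) is
    (1−αx)(1−αy)·r(m,n) + αx(1−αy)·r(m+1,n) + (1−αx)αy·r(m,n+1)
    + αxαy·r(m+1,n+1); F_Avg is a stride-1 2×2 mean filter (edge
    replicated), disabled with ``apply_avg=False``.
    """
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    x, was = _wrap(r)
    _, _, H, W = x.data.shape
    Rm = resample_matrix(H, scale, "bilinear", alpha=alpha_y)
    Cm = resample_matrix(W, scale, "bilinear", alpha=alpha_x)
    if apply_avg:
        Rm = avg2x2_matrix(Rm.shape[0]) @ Rm
        Cm = avg2x2_matrix(Cm.shape[0]) @ Cm
    return _unwrap(ag.resize2d(x, Rm, Cm), was)
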