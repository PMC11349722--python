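"""Slow nested-loop reference implementations used only by the tests.

Deliberately written with explicit python loops and their own padding /
interpolation arithmetic so they stay independent of the vectorized
implementations they check.  All convolutions are cross-correlations.
"""

import numpy as np


def _pad_image(img, ph, pw, mode):
    if mode == "zeros":
        return np.pad(img, ((ph, ph), (pw, pw)))
    if mode == "reflect":
        return np.pad(img, ((ph, ph), (pw, pw)), mode="reflect")
    if mode == "edge":
        return np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
    raise ValueError(mode)


def conv2d_loops(x, w, b=None, stride=1, dilation=1, pad=None, mode="zeros"):
    """Dense convolution, one multiply at a time. x: (N,C,H,W), w: (O,C,kh,kw)."""
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    assert Cw == C
    if pad is None:
        ph, pw = dilation * (kh - 1) // 2, dilation * (kw - 1) // 2
    else:
        ph = pw = pad
    Ho = (H + 2 * ph - (dilation * (kh - 1) + 1)) // stride + 1
    Wo = (W + 2 * pw - (dilation * (kw - 1) + 1)) // stride + 1
    out = np.zeros((N, O, Ho, Wo))
    for n in range(N):
        xp = np.stack([_pad_image(x[n, c], ph, pw, mode) for c in range(C)])
        for o in range(O):
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(C):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (
                                    xp[c, i * stride + u * dilation,
                                       j * stride + v * dilation]
                                    * w[o, c, u, v]
                                )
                    out[n, o, i, j] = acc + (0.0 if b is None else b[o])
    return out


def depthwise_conv_loops(x, w, b=None):
    """Per-channel convolution; w: (C,1,kh,kw), same zero padding."""
    N, C, H, W = x.shape
    out = np.zeros_like(x)
    for c in range(C):
        out[:, c:c + 1] = conv2d_loops(
            x[:, c:c + 1], w[c:c + 1], None if b is None else b[c:c + 1]
        )
    return out


def pointwise_conv_loops(x, w, b=None):
    """Per-pixel channel mixing; w: (O,C)."""
    N, C, H, W = x.shape
    O = w.shape[0]
    out = np.zeros((N, O, H, W))
    for n in range(N):
        for i in range(H):
            for j in range(W):
                out[n, :, i, j] = w @ x[n, :, i, j] + (0.0 if b is None else b)
    return out


def keys_cubic_scalar(t, a=-0.5):
    t = abs(float(t))
    if t <= 1:
        return (a + 2) * t ** 3 - (a + 3) * t ** 2 + 1
    if t < 2:
        return a * t ** 3 - 5 * a * t ** 2 + 8 * a * t - 4 * a
    return 0.0


def bicubic_upsample_loops(x, scale, a=-0.5):
    """16-tap weighted sum per output pixel; edge-clamped borders."""
    N, C, H, W = x.shape
    Ho, Wo = round(H * scale), round(W * scale)
    out = np.zeros((N, C, Ho, Wo))
    for n in range(N):
        for c in range(C):
            for i in range(Ho):
                sy = (i + 0.5) / scale - 0.5
                by = int(np.floor(sy))
                for j in range(Wo):
                    sx = (j + 0.5) / scale - 0.5
                    bx = int(np.floor(sx))
                    acc = 0.0
                    for u in (-1, 0, 1, 2):
                        wy = keys_cubic_scalar(sy - (by + u), a)
                        iy = min(max(by + u, 0), H - 1)
                        for v in (-1, 0, 1, 2):
                            wx = keys_cubic_scalar(sx - (bx + v), a)
                            ix = min(max(bx + v, 0), W - 1)
                            acc += x[n, c, iy, ix] * wy * wx
                    out[n, c, i, j] = acc
    return out


def reflect_conv_loops(x, w, b=None):
    """Single same-size convolution with reflection padding."""
    return conv2d_loops(x, w, b, mode="reflect")


def mean2x2_loops(x):
    """Stride-1 2×2 mean filter, bottom/right edge replicated."""
    N, C, H, W = x.shape
    out = np.zeros_like(x)
    for n in range(N):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    i2, j2 = min(i + 1, H - 1), min(j + 1, W - 1)
                    out[n, c, i, j] = 0.25 * (
                        x[n, c, i, j] + x[n, c, i2, j]
                        + x[n, c, i, j2] + x[n, c, i2, j2]
                    )
    return out


def bilinear_upsample_loops(x, scale, apply_avg=True):
    """4-tap bilinear blend per output pixel, then optional 2×2 mean."""
    N, C, H, W = x.shape
    Ho, Wo = round(H * scale), round(W * scale)
    out = np.zeros((N, C, Ho, Wo))
    for n in range(N):
        for c in range(C):
            for i in range(Ho):
                sy = (i + 0.5) / scale - 0.5
                m = int(np.floor(sy))
                ay = sy - m
                m0, m1 = min(max(m, 0), H - 1), min(max(m + 1, 0), H - 1)
                for j in range(Wo):
                    sx = (j + 0.5) / scale - 0.5
                    k = int(np.floor(sx))
                    ax = sx - k
                    k0, k1 = min(max(k, 0), W - 1), min(max(k + 1, 0), W - 1)
                    out[n, c, i, j] = (
                        (1 - ax) * (1 - ay) * x[n, c, m0, k0]
                        + ax * (1 - ay) * x[n, c, m0, k1]
                        + (1 - ax) * ay * x[n, c, m1, k0]
                        + ax * ay * x[n, c, m1, k1]
                    )
    return mean2x2_loops(out) if apply_avg else out


def avg_pool_loops(x, k, stride=1):
    """Same-size average pooling with zero padding (count includes pad)."""
    C = x.shape[1]
    w = np.zeros((C, 1, k, k)) + 1.0 / (k * k)
    out = np.zeros_like(x)
    for c in range(C):
        out[:, c:c + 1] = conv2d_loops(x[:, c:c + 1], w[c:c + 1], stride=stride)
    return out


def cross_entropy_loops(logits, target):
    """Mean per-pixel softmax cross-entropy, one pixel at a time."""
    N, K, H, W = logits.shape
    total = 0.0
    for n in range(N):
        for i in range(H):
            for j in range(W):
                z = logits[n, :, i, j]
                z = z - z.max()
                p = np.exp(z) / np.exp(z).sum()
                total += -np.log(p[int(target[n, i, j])])
    return total / (N * H * W)
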