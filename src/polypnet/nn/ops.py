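"""Low-level array operations for the CNN layers.

All feature maps use NHWC layout (batch, height, width, channels), float32.
Convolutions here follow the strict signal-processing orientation — the
kernel is flipped before the sliding inner product — so that a layer's
output equals the textbook double-sum ``sum_p sum_q I(p,q) K(x-p+1, y-q+1)``
evaluated with the very same weight array.  For learned kernels orientation
is immaterial, but it lets brute-force oracles use one formula.

The sliding product is computed tap-wise: one BLAS matmul per kernel
offset, accumulated into the output.  This avoids materialising a full
im2col buffer (which for a 480x640x16 map would run to hundreds of MB) and
keeps single-thread throughput close to the GEMM peak.
"""

from __future__ import annotations

import numpy as np


def _flip2(w: np.ndarray) -> np.ndarray:
    """Flip a (kh, kw, cin, cout) kernel along both spatial axes."""
    return w[::-1, ::-1]


def cross_correlate_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same'-padded stride-1 cross-correlation of NHWC ``x`` with ``w``.

    ``w`` has shape (kh, kw, cin, cout) with odd kh, kw.  Output spatial
    dims equal input spatial dims.
    """
    n, h, wd, c = x.shape
    kh, kw, cin, cout = w.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {cin}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dims must be odd for 'same' padding")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n * h * wd, cout), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            tap = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
            out += tap.reshape(-1, c) @ w[i, j]
    return out.reshape(n, h, wd, cout)


def conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """True convolution (flipped kernel), 'same' padding, stride 1."""
    return cross_correlate_same(x, _flip2(w))


def conv2d_same_backward(
    x: np.ndarray, w: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``conv2d_same`` w.r.t. input and kernel.

    Returns (gx, gw) with the same shapes as (x, w).
    """
    n, h, wd, c = x.shape
    kh, kw, cin, cout = w.shape
    ph, pw = kh // 2, kw // 2
    wf = _flip2(w)  # the kernel actually slid in the forward pass
    # d/dx: correlate gy with wf flipped back (= w) and channels swapped.
    gx = cross_correlate_same(gy, w.transpose(0, 1, 3, 2).copy())
    # d/dwf tap (i, j): inner product of the shifted input with gy.
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    gyf = gy.reshape(-1, cout)
    gwf = np.empty_like(wf)
    for i in range(kh):
        for j in range(kw):
            tap = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
            gwf[i, j] = tap.reshape(-1, c).T @ gyf
    return gx, _flip2(gwf)


def conv1x1(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pointwise convolution: (cin, cout) weight applied at every pixel."""
    n, h, wd, c = x.shape
    y = x.reshape(-1, c) @ w
    if b is not None:
        y += b
    return y.reshape(n, h, wd, -1)


def pool_windows(x: np.ndarray, size: int, stride: int):
    """Strided (non-copying) view of pooling windows.

    Returns (windows, h_out, w_out) where windows has shape
    (n, h_out, w_out, c, size, size).  Requires a C-contiguous input.
    """
    n, h, w, c = x.shape
    if size > h or size > w:
        raise ValueError(f"pooling window {size} exceeds input dims {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be positive")
    ho = (h - size) // stride + 1
    wo = (w - size) // stride + 1
    sn, sh, sw, sc = x.strides
    shape = (n, ho, wo, c, size, size)
    strides = (sn, sh * stride, sw * stride, sc, sh, sw)
    return np.lib.stride_tricks.as_strided(x, shape, strides), ho, wo


def max_pool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Windowed maximum; output dims floor((D - size)/stride) + 1."""
    x = np.ascontiguousarray(x)
    win, _, _ = pool_windows(x, size, stride)
    return win.max(axis=(4, 5))


def max_pool_backward(
    x: np.ndarray, y: np.ndarray, gy: np.ndarray, size: int, stride: int
) -> np.ndarray:
    """Route gradient to window maxima (ties share the gradient equally).

    Valid for the non-overlapping case stride >= size, which is the only
    geometry the architectures here use.
    """
    if stride < size:
        raise ValueError("overlapping pooling backward not supported")
    x = np.ascontiguousarray(x)
    gx = np.zeros_like(x)
    win, ho, wo = pool_windows(x, size, stride)
    gwin, _, _ = pool_windows(gx, size, stride)  # writable view, disjoint windows
    mask = win == y[..., None, None]
    share = gy / mask.sum(axis=(4, 5))
    gwin += mask * share[..., None, None]
    return gx


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along ``axis``."""
    z = np.asarray(z, dtype=np.float64)
    m = z.max(axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)
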