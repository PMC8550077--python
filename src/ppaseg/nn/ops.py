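"""Structured differentiable operations: convolution, pooling, batch
normalisation and bilinear resampling, in NCHW layout.

Convolution uses a kernel-offset decomposition: a k×k convolution is the
sum of k² strided GEMMs, which keeps peak memory at one feature map rather
than a full im2col buffer.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d", "max_pool2d", "avg_pool2d", "adaptive_avg_pool2d",
    "batch_norm", "resize_bilinear",
]


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (O,C,kh,kw), b: (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    if OH < 1 or OW < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data

    out = np.zeros((N, OH, OW, O), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + sh * (OH - 1) + 1:sh, j:j + sw * (OW - 1) + 1:sw]
            # (N,C,OH,OW) x (O,C) -> (N,OH,OW,O)
            out += np.tensordot(xs, w.data[:, :, i, j], axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        b = as_tensor(b)
        out += b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,OH,OW,O)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                hs = slice(i, i + sh * (OH - 1) + 1, sh)
                ws_ = slice(j, j + sw * (OW - 1) + 1, sw)
                if gw is not None:
                    xs = xp[:, :, hs, ws_]
                    # (N,OH,OW,O) x (N,C,OH,OW) -> (O,C)
                    gw[:, :, i, j] = np.tensordot(
                        gt, xs, axes=([0, 1, 2], [0, 2, 3]))
                if need_x:
                    # (N,OH,OW,O) x (O,C) -> (N,OH,OW,C)
                    gxp[:, :, hs, ws_] += np.tensordot(
                        gt, w.data[:, :, i, j], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
        if gw is not None:
            w._accum(gw)
        if need_x:
            gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel_size, stride=None, padding=0) -> Tensor:
    x = as_tensor(x)
    kh, kw = _pair(kernel_size)
    sh, sw = _pair(stride if stride is not None else kernel_size)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    xp = (np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                 constant_values=-np.inf) if (ph or pw) else x.data)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw][:, :, :OH, :OW].reshape(N, C, OH, OW, kh * kw)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
        n_i, c_i, oh_i, ow_i = np.indices((N, C, OH, OW))
        h_idx = oh_i * sh + arg // kw
        w_idx = ow_i * sw + arg % kw
        np.add.at(gxp, (n_i, c_i, h_idx, w_idx), g)
        x._accum(gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp)

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling by an integer factor."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    f = int(factor)
    if H % f or W % f:
        raise ValueError(f"avg_pool2d: size ({H},{W}) not divisible by {f}")
    out = x.data.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (f * f), (N, C, H // f, f, W // f, f))
        x._accum(gx.reshape(N, C, H, W))

    return Tensor._make(out, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Mean pooling to a target size; requires an integer reduction factor."""
    x = as_tensor(x)
    _, _, H, W = x.data.shape
    oh, ow = out_hw
    if (H, W) == (oh, ow):
        return x
    if H % oh or W % ow or H // oh != W // ow:
        raise ValueError(
            f"adaptive_avg_pool2d: ({H},{W}) -> ({oh},{ow}) is not an "
            "integer isotropic reduction")
    return avg_pool2d(x, H // oh)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N,H,W).

    In training mode the batch statistics are used and the running buffers
    are updated in place; in eval mode the running buffers are used.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    N, C, H, W = x.data.shape
    m = N * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        # unbiased variance feeds the running buffer, as is conventional
        running_var *= 1.0 - momentum
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv_std.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gam = gamma.data.reshape(1, C, 1, 1)
        istd = inv_std.reshape(1, C, 1, 1)
        if training:
            dxhat = g * gam
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = istd * (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m)
        else:
            gx = g * gam * istd
        x._accum(gx)

    return Tensor._make(out, (x, gamma, beta), backward)


def _linear_coords(in_size: int, out_size: int):
    """Source coordinates for align_corners=False bilinear resampling."""
    scale = in_size / out_size
    src = (np.arange(out_size, dtype=np.float64) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, in_size - 1.0)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, in_size - 1)
    frac = (src - i0).astype(np.float32)
    return i0, i1, frac


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling (align_corners=False), differentiable."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    oh, ow = out_hw
    if (H, W) == (oh, ow):
        return x
    h0, h1, fh = _linear_coords(H, oh)
    w0, w1, fw = _linear_coords(W, ow)
    fhc = fh[None, None, :, None]
    fwc = fw[None, None, None, :]
    tmp = x.data[:, :, h0, :] * (1.0 - fhc) + x.data[:, :, h1, :] * fhc
    out = tmp[:, :, :, w0] * (1.0 - fwc) + tmp[:, :, :, w1] * fwc

    def backward(g):
        gtmp = np.zeros((N, C, oh, W), dtype=np.float32)
        sl = (slice(None), slice(None), slice(None))
        np.add.at(gtmp, sl + (w0,), g * (1.0 - fwc))
        np.add.at(gtmp, sl + (w1,), g * fwc)
        gx = np.zeros((N, C, H, W), dtype=np.float32)
        sl2 = (slice(None), slice(None))
        np.add.at(gx, sl2 + (h0,), gtmp * (1.0 - fhc))
        np.add.at(gx, sl2 + (h1,), gtmp * fhc)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)
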