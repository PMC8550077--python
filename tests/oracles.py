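"""Independent straight-line oracles used by the tests.

Everything here is written as naive per-pixel loops (or O(n^2) pair
counts), deliberately sharing no code with the package implementation.
Sizes are kept tiny so the loops stay fast.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-7


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(P, B, reduction="mean"):
    P = np.asarray(P, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    total = 0.0
    h, w = P.shape
    for y in range(h):
        for x in range(w):
            p = min(max(P[y, x], EPS), 1.0 - EPS)
            total += -(B[y, x] * math.log(p) + (1 - B[y, x]) * math.log(1 - p))
    return total / (h * w) if reduction == "mean" else total


def iou_loss(P, B):
    P = np.asarray(P, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    inter = union = 0.0
    h, w = P.shape
    for y in range(h):
        for x in range(w):
            inter += P[y, x] * B[y, x]
            union += P[y, x] + B[y, x] - P[y, x] * B[y, x]
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def weight_map(B, kernel, gain=5.0):
    """Zero-padded count-including sliding average, exhaustive windows."""
    B = np.asarray(B, dtype=np.float64)
    h, w = B.shape
    p = kernel // 2
    out = np.zeros_like(B)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-p, p + 1):
                for dx in range(-p, p + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        acc += B[yy, xx]
            out[y, x] = 1.0 + gain * abs(acc / (kernel * kernel) - B[y, x])
    return out


def weighted_iou_loss(P, B, W):
    P, B, W = (np.asarray(a, dtype=np.float64) for a in (P, B, W))
    inter = total = 0.0
    h, w = P.shape
    for y in range(h):
        for x in range(w):
            inter += W[y, x] * P[y, x] * B[y, x]
            total += W[y, x] * (P[y, x] + B[y, x])
    return 1.0 - (inter + 1.0) / (total - inter + 1.0)


def weighted_bce_loss(P, B, W):
    P, B, W = (np.asarray(a, dtype=np.float64) for a in (P, B, W))
    num = den = 0.0
    h, w = P.shape
    for y in range(h):
        for x in range(w):
            p = min(max(P[y, x], EPS), 1.0 - EPS)
            ell = -(B[y, x] * math.log(p) + (1 - B[y, x]) * math.log(1 - p))
            num += ell * W[y, x]
            den += W[y, x]
    return num / den


def seg_loss(P, B, kernel=31, gain=5.0):
    W = weight_map(B, kernel, gain)
    return weighted_iou_loss(P, B, W) + weighted_bce_loss(P, B, W)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_pair_count(scores, labels):
    """(concordant + 0.5 * ties) / (n_pos * n_neg), O(n^2)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    acc = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                acc += 1.0
            elif sp == sn:
                acc += 0.5
    return acc / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# network building blocks (eval-mode forward only)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride=1, padding=0):
    """x (C,H,W), w (O,C,k,k); explicit quintuple loop."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    C, H, W_ = x.shape
    O, _, kh, kw = w.shape
    oh = (H + 2 * padding - kh) // stride + 1
    ow = (W_ + 2 * padding - kw) // stride + 1
    out = np.zeros((O, oh, ow))
    for o in range(O):
        for yo in range(oh):
            for xo in range(ow):
                acc = 0.0
                for c in range(C):
                    for i in range(kh):
                        for j in range(kw):
                            yy = yo * stride + i - padding
                            xx = xo * stride + j - padding
                            if 0 <= yy < H and 0 <= xx < W_:
                                acc += x[c, yy, xx] * w[o, c, i, j]
                out[o, yo, xo] = acc + (b[o] if b is not None else 0.0)
    return out


def batchnorm_eval(x, gamma, beta, rm, rv, eps=1e-5):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - rm[c]) / math.sqrt(rv[c] + eps) * gamma[c] + beta[c]
    return out


def convbn_eval(x, layer, relu=None):
    """Run a package ConvBN layer's weights through the naive routines."""
    out = conv2d(x, layer.conv.weight.data,
                 None if layer.conv.bias is None else layer.conv.bias.data,
                 stride=layer.conv.stride, padding=layer.conv.padding)
    out = batchnorm_eval(out, layer.bn.gamma.data, layer.bn.beta.data,
                         layer.bn.running_mean, layer.bn.running_var,
                         eps=layer.bn.eps)
    use_relu = layer.relu if relu is None else relu
    return np.maximum(out, 0.0) if use_relu else out


def conv_plain(x, layer):
    """Plain Conv2d layer via the naive conv."""
    return conv2d(x, layer.weight.data,
                  None if layer.bias is None else layer.bias.data,
                  stride=layer.stride, padding=layer.padding)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def resize_bilinear(x, oh, ow):
    """align_corners=False bilinear resize, per-pixel loops. x: (C,H,W)."""
    x = np.asarray(x, dtype=np.float64)
    C, H, W_ = x.shape
    out = np.zeros((C, oh, ow))
    for c in range(C):
        for yo in range(oh):
            sy = min(max((yo + 0.5) * H / oh - 0.5, 0.0), H - 1.0)
            y0 = int(math.floor(sy))
            y1 = min(y0 + 1, H - 1)
            fy = sy - y0
            for xo in range(ow):
                sx = min(max((xo + 0.5) * W_ / ow - 0.5, 0.0), W_ - 1.0)
                x0 = int(math.floor(sx))
                x1 = min(x0 + 1, W_ - 1)
                fx = sx - x0
                top = x[c, y0, x0] * (1 - fx) + x[c, y0, x1] * fx
                bot = x[c, y1, x0] * (1 - fx) + x[c, y1, x1] * fx
                out[c, yo, xo] = top * (1 - fy) + bot * fy
    return out


def avg_pool(x, factor):
    x = np.asarray(x, dtype=np.float64)
    C, H, W_ = x.shape
    oh, ow = H // factor, W_ // factor
    out = np.zeros((C, oh, ow))
    for c in range(C):
        for yo in range(oh):
            for xo in range(ow):
                out[c, yo, xo] = x[c, yo * factor:(yo + 1) * factor,
                                   xo * factor:(xo + 1) * factor].mean()
    return out


def mask_inner_boundary(mask):
    """Brute-force: a mask pixel is boundary if any 4-neighbour is 0."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    out[y, x] = True
                    break
    return out.astype(np.uint8)
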