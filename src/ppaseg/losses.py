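"""Boundary-weighted segmentation losses with deep supervision.

The training signal combines, per side output, a weighted soft-IoU term
and a weighted binary cross-entropy term, where the per-pixel weight

    weight = 1 + gain * |AVG(B) - B|,      gain = 5 by default,

is large wherever a sliding-window mean of the ground-truth mask disagrees
with the mask itself — i.e. in a band around the lesion boundary, the
"complex" pixels. AVG is a same-size average pooling (zero padding counted
in the mean), so the weight lies in [1, 1 + gain].

The weighted IoU follows the structure-loss convention: with
inter = sum(W*P*B) and total = sum(W*(P+B)),

    L_IoU_w = 1 - (inter + 1) / (total - inter + 1),

which is 0 exactly at a perfect binary prediction. The weighted BCE is the
weighted mean sum(W * bce) / sum(W). The total deep-supervision loss adds
an edge-map BCE on the edge-attention side output and a weighted
segmentation loss for the global map and each reverse-attention side
output, all upsampled to ground-truth resolution.

All loss functions accept either NumPy arrays (returning floats) or
autograd Tensors for the prediction (returning a Tensor so gradients can
flow); masks and weight maps are always plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .nn import Tensor

__all__ = [
    "EPS", "PoolingSpec", "WeightMap", "LossReport",
    "boundary_weight_map", "edge_loss", "plain_bce_loss", "plain_iou_loss",
    "weighted_bce_loss", "weighted_iou_loss", "seg_loss", "total_loss",
]

EPS = 1e-7  # probability clamp before logarithms


@dataclass(frozen=True)
class PoolingSpec:
    """Average-pooling geometry; output sizes follow the floor formula
    H_out = floor((H_in + 2 p - k) / s) + 1 (same for width)."""

    kernel_size: tuple[int, int] = (31, 31)
    stride: tuple[int, int] = (1, 1)
    padding: tuple[int, int] = (15, 15)

    def output_size(self, h_in: int, w_in: int) -> tuple[int, int]:
        (kh, kw), (sh, sw), (ph, pw) = (self.kernel_size, self.stride,
                                        self.padding)
        return ((h_in + 2 * ph - kh) // sh + 1,
                (w_in + 2 * pw - kw) // sw + 1)

    def validate_same_size(self, h: int, w: int) -> None:
        if self.output_size(h, w) != (h, w):
            raise ValueError(
                f"pooling {self.kernel_size}/{self.stride}/{self.padding} "
                f"changes the map size {self.output_size(h, w)} != {(h, w)}; "
                "the weight map needs H_out = H_in, W_out = W_in "
                "(k = 2p + 1, stride 1)")

    @staticmethod
    def same_size(kernel: int = 31) -> "PoolingSpec":
        if kernel % 2 == 0:
            raise ValueError("same-size pooling needs an odd kernel")
        return PoolingSpec((kernel, kernel), (1, 1),
                           (kernel // 2, kernel // 2))


@dataclass(frozen=True)
class WeightMap:
    weights: np.ndarray

    def __post_init__(self):
        w = self.weights
        if w.min() < 1.0 - 1e-6:
            raise ValueError("weight map must be >= 1 everywhere")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), got values {vals[:5]}")
    return arr.astype(np.float32)


def _as_prob(p, clamp: bool) -> tuple[Tensor, bool]:
    """Wrap the prediction; report whether the caller passed plain arrays."""
    was_array = not isinstance(p, Tensor)
    t = Tensor(p) if was_array else p
    if clamp:
        t = t.clip(EPS, 1.0 - EPS)
    return t, was_array

def _ret(value: Tensor, was_array: bool):
    return value.item() if was_array else value

def _shape_check(p: Tensor, b: np.ndarray) -> None:
    if tuple(p.shape[-2:]) != tuple(b.shape[-2:]):
        raise ValueError(f"prediction {tuple(p.shape)} and mask "
                         f"{tuple(b.shape)} spatial sizes differ")


def _flatten_hw(t: Tensor) -> Tensor:
    """(...,H,W) -> (batch, H*W); a bare (H,W) map becomes one row."""
    h, w = t.shape[-2], t.shape[-1]
    n = int(np.prod(t.shape[:-2])) if t.ndim > 2 else 1
    return t.reshape(n, h * w)


def boundary_weight_map(B, pool: PoolingSpec | None = None,
                        gain: float = 5.0) -> np.ndarray:
    """Per-pixel loss weights 1 + gain*|AVG(B) - B| (values in [1, 1+gain]).

    ``B`` may be (H,W) or batched (...,H,W); the sliding mean is computed
    per 2-D map with zero padding counted in the average.
    """
    pool = pool or PoolingSpec()
    B = _check_binary(B, "mask")
    pool.validate_same_size(B.shape[-2], B.shape[-1])
    if pool.kernel_size[0] != pool.kernel_size[1]:
        raise ValueError("weight-map pooling kernel must be square")
    k = pool.kernel_size[0]
    # uniform_filter with constant 0 boundary == count-including zero-padded
    # average pooling with k = 2p+1, stride 1
    size = (1,) * (B.ndim - 2) + (k, k)
    avg = uniform_filter(B, size=size, mode="constant", cval=0.0)
    return (1.0 + gain * np.abs(avg - B)).astype(np.float32)


def _bce_map(p: Tensor, b: np.ndarray) -> Tensor:
    bt = Tensor(b)
    return -(bt * p.log() + (1.0 - bt) * (1.0 - p).log())


def plain_bce_loss(P, B, reduction: str = "mean"):
    """Binary cross-entropy over pixels (mean by default)."""
    B = _check_binary(B, "mask")
    p, was_array = _as_prob(P, clamp=True)
    _shape_check(p, B)
    ell = _bce_map(p, np.broadcast_to(B, p.shape))
    out = ell.mean() if reduction == "mean" else ell.sum()
    return _ret(out, was_array)


def edge_loss(S_e, G_e, reduction: str = "mean"):
    """BCE between the (sigmoid-activated) edge side output and the edge map."""
    return plain_bce_loss(S_e, G_e, reduction=reduction)


def plain_iou_loss(P, B):
    """Soft Jaccard loss 1 - |A∩B| / |A∪B| (per sample, then averaged)."""
    B = np.asarray(B, dtype=np.float32)
    p, was_array = _as_prob(P, clamp=False)
    _shape_check(p, B)
    pf = _flatten_hw(p)
    bf = _flatten_hw(Tensor(np.broadcast_to(B, p.shape))).data
    inter = (pf * Tensor(bf)).sum(axis=1)
    union = pf.sum(axis=1) + Tensor(bf.sum(axis=1)) - inter
    # guard the empty-empty case: 0/0 union counts as perfect agreement
    denom = Tensor(np.maximum(union.data, np.float32(EPS)))
    out = (1.0 - inter / denom).mean()
    return _ret(out, was_array)


def weighted_iou_loss(P, B, W=None, pool: PoolingSpec | None = None,
                      gain: float = 5.0):
    """Boundary-weighted soft IoU loss (structure-loss convention)."""
    B = _check_binary(B, "mask")
    p, was_array = _as_prob(P, clamp=False)
    _shape_check(p, B)
    if W is None:
        W = boundary_weight_map(B, pool, gain=gain)
    W = np.asarray(W.weights if isinstance(W, WeightMap) else W,
                   dtype=np.float32)
    if W.shape[-2:] != B.shape[-2:]:
        raise ValueError("weight map size differs from mask size")
    bb = np.broadcast_to(B, p.shape)
    ww = np.broadcast_to(W, p.shape)
    inter = _flatten_hw(p * Tensor(ww * bb)).sum(axis=1)
    total = _flatten_hw((p + Tensor(bb)) * Tensor(ww)).sum(axis=1)
    out = (1.0 - (inter + 1.0) / (total - inter + 1.0)).mean()
    return _ret(out, was_array)


def weighted_bce_loss(P, B, W=None, pool: PoolingSpec | None = None,
                      gain: float = 5.0):
    """Boundary-weighted BCE: sum(W * bce) / sum(W), per sample."""
    B = _check_binary(B, "mask")
    p, was_array = _as_prob(P, clamp=True)
    _shape_check(p, B)
    if W is None:
        W = boundary_weight_map(B, pool, gain=gain)
    W = np.asarray(W.weights if isinstance(W, WeightMap) else W,
                   dtype=np.float32)
    bb = np.broadcast_to(B, p.shape)
    ww = np.broadcast_to(W, p.shape).astype(np.float32)
    ell = _bce_map(p, bb)
    num = _flatten_hw(ell * Tensor(ww)).sum(axis=1)
    den = _flatten_hw(Tensor(ww)).data.sum(axis=1)
    out = (num / Tensor(den)).mean()
    return _ret(out, was_array)


def seg_loss(P, B, pool: PoolingSpec | None = None, gain: float = 5.0):
    """Weighted IoU + weighted BCE with a shared boundary weight map."""
    Bb = _check_binary(B, "mask")
    W = boundary_weight_map(Bb, pool, gain=gain)
    p, was_array = _as_prob(P, clamp=False)
    out = (weighted_iou_loss(p, Bb, W)
           + weighted_bce_loss(p, Bb, W))
    return _ret(out, was_array)


@dataclass
class LossReport:
    """Per-term decomposition of the deep-supervision objective."""

    l_edge: float
    l_seg_g: float
    l_seg: dict[int, float]  # keyed by pyramid level 5, 4, 3
    l_total: float
    tensor: Tensor | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        d = {"l_edge": self.l_edge, "l_seg_g": self.l_seg_g,
             "l_total": self.l_total}
        d.update({f"l_seg_{i}": v for i, v in self.l_seg.items()})
        return d


def total_loss(outputs: dict, G_s, G_e, pool: PoolingSpec | None = None,
               gain: float = 5.0, reduction: str = "mean") -> LossReport:
    """Deep-supervision objective over the upsampled side outputs.

    ``outputs`` must carry probabilities (or upsampled logit Tensors under
    the ``*_up`` keys of the network dict, in which case sigmoids are
    applied here): keys S_e, S_g, S_5, S_4, S_3.
    """
    def fetch(key):
        if key + "_up" in outputs:
            return outputs[key + "_up"].sigmoid()
        if key in outputs:
            v = outputs[key]
            return v if isinstance(v, Tensor) else Tensor(v)
        raise ValueError(f"missing side output {key!r}")

    G_s = _check_binary(G_s, "lesion mask")
    G_e = _check_binary(G_e, "edge mask")
    le = edge_loss(fetch("S_e"), G_e, reduction=reduction)
    lg = seg_loss(fetch("S_g"), G_s, pool=pool, gain=gain)
    per_level = {i: seg_loss(fetch(f"S_{i}"), G_s, pool=pool, gain=gain)
                 for i in (5, 4, 3)}
    lt = le + lg
    for v in per_level.values():
        lt = lt + v
    return LossReport(
        l_edge=float(le.item() if isinstance(le, Tensor) else le),
        l_seg_g=float(lg.item() if isinstance(lg, Tensor) else lg),
        l_seg={i: float(v.item() if isinstance(v, Tensor) else v)
               for i, v in per_level.items()},
        l_total=float(lt.item() if isinstance(lt, Tensor) else lt),
        tensor=lt if isinstance(lt, Tensor) else None,
    )
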