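"""Feature-expression-enhancement decoder: edge attention, parallel
partial decoder and cascaded reverse attention.

The network taps a five-level encoder pyramid. The f2 level (stride 4)
feeds an edge-attention branch whose side output is supervised by the
lesion-boundary map. Levels f3..f5 are fused by the parallel partial
decoder into a coarse global map S_g. Three reverse-attention stages then
refine the prediction from coarse to fine (level 5 -> 4 -> 3): each stage
attends to what the coarser prediction has NOT yet claimed
(A_i = 1 - sigmoid(S_higher)), gates the reduced encoder feature with it,
concatenates the downsampled edge feature, and adds its 1-channel
projection back onto the coarser map (residual refinement). The final
probability map is sigmoid(upsample(S_3)).
"""

from __future__ import annotations

import numpy as np

from .backbones import BackboneSpec, FeaturePyramid, build_backbone
from .nn import (Conv2d, ConvBN, Module, Tensor, adaptive_avg_pool2d,
                 concat, resize_bilinear)

__all__ = ["EdgeAttention", "PartialDecoder", "ReverseAttention", "OTUnet",
           "assemble_ot_unet"]


class EdgeAttention(Module):
    """Contour branch on the stride-4 feature map.

    Two 3x3 conv+BN+ReLU stages reduce f2 to ``reduce`` channels (the
    edge-attention feature ``e_att`` shared with every reverse-attention
    stage); a 1x1 projection yields the edge logit map S_e.
    """

    def __init__(self, c2: int, rng, reduce: int = 32):
        super().__init__()
        self.c1 = ConvBN(c2, reduce, 3, rng, padding=1)
        self.c2 = ConvBN(reduce, reduce, 3, rng, padding=1)
        self.head = Conv2d(reduce, 1, 1, rng)

    def forward(self, f2: Tensor) -> tuple[Tensor, Tensor]:
        e_att = self.c2(self.c1(f2))
        return e_att, self.head(e_att)


class PartialDecoder(Module):
    """Parallel partial decoder fusing the three high-level features.

    Each level is reduced to ``reduce`` channels by 1x1 conv+BN, then
    gated top-down multiplicatively: the coarser maps are convolved,
    upsampled and multiplied into the finer ones, so coarse evidence masks
    the fine features. The three gated maps are upsampled to the f3 grid,
    concatenated, and projected to the 1-channel global logit map S_g.
    """

    def __init__(self, c3: int, c4: int, c5: int, rng, reduce: int = 32):
        super().__init__()
        self.r3 = ConvBN(c3, reduce, 1, rng, relu=False)
        self.r4 = ConvBN(c4, reduce, 1, rng, relu=False)
        self.r5 = ConvBN(c5, reduce, 1, rng, relu=False)
        # transform convs feeding the multiplicative gates
        self.t54 = ConvBN(reduce, reduce, 3, rng, padding=1, relu=False)
        self.t53 = ConvBN(reduce, reduce, 3, rng, padding=1, relu=False)
        self.t43 = ConvBN(reduce, reduce, 3, rng, padding=1, relu=False)
        self.fuse = ConvBN(3 * reduce, reduce, 3, rng, padding=1, relu=False)
        self.head = Conv2d(reduce, 1, 1, rng)

    def forward(self, f3: Tensor, f4: Tensor, f5: Tensor) -> Tensor:
        hw3 = (f3.shape[2], f3.shape[3])
        hw4 = (f4.shape[2], f4.shape[3])
        g3, g4, g5 = self.r3(f3), self.r4(f4), self.r5(f5)
        g4p = g4 * resize_bilinear(self.t54(g5), hw4)
        g3p = (g3 * resize_bilinear(self.t43(g4), hw3)
               * resize_bilinear(self.t53(g5), hw3))
        cat = concat([g3p, resize_bilinear(g4p, hw3),
                      resize_bilinear(g5, hw3)], axis=1)
        return self.head(self.fuse(cat))


class ReverseAttention(Module):
    """One reverse-attention refinement stage at pyramid level i.

    A_i = 1 - sigmoid(S_higher resized to the level grid) highlights the
    regions the coarser prediction missed; it gates the 1x1-reduced
    encoder feature. The edge-attention feature is mean-pooled down to the
    level grid and concatenated. Two 3x3 conv+BN+ReLU stages and a 1x1
    projection produce a correction that is added to the resized coarser
    logits.
    """

    def __init__(self, ci: int, rng, reduce: int = 32, edge_ch: int = 32):
        super().__init__()
        self.reduce = Conv2d(ci, reduce, 1, rng)
        self.c1 = ConvBN(reduce + edge_ch, reduce, 3, rng, padding=1)
        self.c2 = ConvBN(reduce, reduce, 3, rng, padding=1)
        self.head = Conv2d(reduce, 1, 1, rng)

    def forward(self, f_i: Tensor, s_higher: Tensor, e_att: Tensor
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (R_i, S_i, A_i)."""
        hw = (f_i.shape[2], f_i.shape[3])
        s_up = resize_bilinear(s_higher, hw)
        a_i = 1.0 - s_up.sigmoid()
        gated = self.reduce(f_i) * a_i
        r_i = concat([gated, adaptive_avg_pool2d(e_att, hw)], axis=1)
        delta = self.head(self.c2(self.c1(r_i)))
        return r_i, delta + s_up, a_i


def reverse_attention(f_i, s_higher, e_att, level: int, rng=None,
                      stage: "ReverseAttention | None" = None):
    """Functional wrapper; ``level`` must be one of the cascade levels."""
    if level not in (3, 4, 5):
        raise ValueError(f"reverse attention level must be 3, 4 or 5, got {level}")
    f_i = f_i if isinstance(f_i, Tensor) else Tensor(f_i)
    s_higher = s_higher if isinstance(s_higher, Tensor) else Tensor(s_higher)
    e_att = e_att if isinstance(e_att, Tensor) else Tensor(e_att)
    if stage is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        stage = ReverseAttention(f_i.shape[1], rng,
                                 edge_ch=e_att.shape[1]).eval()
    r_i, s_i, _ = stage(f_i, s_higher, e_att)
    return r_i, s_i


class OTUnet(Module):
    """Edge-attention / partial-decoder / reverse-attention segmenter.

    ``forward`` returns a dict with the side-output logit maps at their
    native grids (S_e at 1/4, S_g at 1/8, S_5 at 1/32, S_4 at 1/16, S_3 at
    1/8), each also upsampled to the input grid (``*_up``), and the final
    probability map ``prob = sigmoid(upsample(S_3))``.
    """

    def __init__(self, spec: BackboneSpec | None = None, seed: int = 0,
                 reduce_channels: int = 32):
        super().__init__()
        self.spec = spec or BackboneSpec()
        self.seed = seed
        self.reduce_channels = reduce_channels
        # decoder weights draw from a stream disjoint from the encoder's
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        self.encoder = build_backbone(self.spec, seed=seed)
        c = self.spec.channel_counts
        rc = reduce_channels
        self.edge = EdgeAttention(c[1], rng, reduce=rc)
        self.pd = PartialDecoder(c[2], c[3], c[4], rng, reduce=rc)
        self.ra5 = ReverseAttention(c[4], rng, reduce=rc, edge_ch=rc)
        self.ra4 = ReverseAttention(c[3], rng, reduce=rc, edge_ch=rc)
        self.ra3 = ReverseAttention(c[2], rng, reduce=rc, edge_ch=rc)

    def forward(self, x, return_attention: bool = False) -> dict:
        from .backbones import _to_batched_3ch
        x = _to_batched_3ch(x)
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(f"input size ({H},{W}) must be divisible by 32")
        pyr: FeaturePyramid = self.encoder(x)
        e_att, s_e = self.edge(pyr.f2)
        s_g = self.pd(pyr.f3, pyr.f4, pyr.f5)
        _, s5, a5 = self.ra5(pyr.f5, s_g, e_att)
        _, s4, a4 = self.ra4(pyr.f4, s5, e_att)
        _, s3, a3 = self.ra3(pyr.f3, s4, e_att)
        out = {"S_e": s_e, "S_g": s_g, "S_5": s5, "S_4": s4, "S_3": s3}
        for k in list(out):
            out[k + "_up"] = resize_bilinear(out[k], (H, W))
        out["prob"] = out["S_3_up"].sigmoid()
        if return_attention:
            out["A"] = {5: a5, 4: a4, 3: a3}
        return out


def assemble_ot_unet(spec: BackboneSpec | None = None, seed: int = 0,
                     reduce_channels: int = 32) -> OTUnet:
    """Build the full segmentation network from a backbone spec."""
    return OTUnet(spec=spec, seed=seed, reduce_channels=reduce_channels)
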