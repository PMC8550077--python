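"""Encoder backbones producing the five-level feature pyramid.

Three interchangeable families are provided — a VGG-style plain
convolutional stack, a residual network with basic blocks, and a
hierarchical-residual (Res2Net-style) network whose bottlenecks split the
mid channels into ``scale`` groups connected in a cascade. Level ``i`` of
the pyramid lives at 1/2^i of the input resolution: the stem provides f1
(stride 2) and four stages provide f2..f5.

Weights are randomly initialised from an explicit seed; previously
exported weights can be loaded from an ``.npz`` archive whose keys match
``Module.state_dict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .nn import (Conv2d, ConvBN, Identity, MaxPool2d, Module, ModuleList,
                 Sequential, Tensor, avg_pool2d, concat)

__all__ = ["BackboneSpec", "FeaturePyramid", "Res2Block", "res2_block",
           "build_backbone", "extract_features", "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS: dict[str, tuple[int, ...]] = {
    "vgg": (64, 128, 256, 512, 512),
    "resnet": (64, 64, 128, 256, 512),
    "res2net": (64, 256, 512, 1024, 2048),
}

# convolutions per VGG stage (VGG-16 layout)
_VGG_DEPTH = (2, 2, 3, 3, 3)


@dataclass
class BackboneSpec:
    """Configuration of the encoder.

    Parameters
    ----------
    variant:
        One of ``vgg``, ``resnet``, ``res2net``.
    channel_counts:
        The five pyramid channel widths c1..c5. ``None`` selects the
        family's canonical widths.
    pretrained:
        If True, ``weights_path`` must point to an ``.npz`` state dict
        exported earlier; no weights are downloaded.
    res2net_scale / res2net_width:
        Number of hierarchical groups ``s`` and the base per-group width
        (at 64 mid-planes) of the res2net bottleneck.
    group1_conv:
        If True the first group of a res2 block is also convolved instead
        of passing through unchanged.
    """

    variant: str = "resnet"
    channel_counts: tuple[int, ...] | None = None
    pretrained: bool = False
    weights_path: str | None = None
    res2net_scale: int = 4
    res2net_width: int = 26
    group1_conv: bool = False
    blocks_per_stage: int = 2

    def __post_init__(self):
        if self.variant not in DEFAULT_CHANNELS:
            raise ValueError(
                f"unknown backbone variant {self.variant!r}; "
                f"choose from {sorted(DEFAULT_CHANNELS)}")
        if self.channel_counts is None:
            self.channel_counts = DEFAULT_CHANNELS[self.variant]
        self.channel_counts = tuple(int(c) for c in self.channel_counts)
        if len(self.channel_counts) != 5:
            raise ValueError("channel_counts must have exactly 5 entries")
        if any(c <= 0 for c in self.channel_counts):
            raise ValueError("channel_counts must be positive")
        if any(a > b for a, b in zip(self.channel_counts,
                                     self.channel_counts[1:])):
            raise ValueError("channel_counts must be non-decreasing")
        if self.res2net_scale < 1:
            raise ValueError("res2net_scale must be >= 1")
        if self.res2net_width < 1:
            raise ValueError("res2net_width must be >= 1")
        if self.pretrained and not self.weights_path:
            raise ValueError(
                "pretrained=True requires weights_path (an .npz state dict); "
                "weights are never downloaded")


class FeaturePyramid(NamedTuple):
    """The five encoder feature maps f1..f5, at strides 2, 4, 8, 16, 32."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor

    @property
    def levels(self) -> tuple[Tensor, ...]:
        return tuple(self)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(f.shape[1] for f in self)

    def validate(self) -> "FeaturePyramid":
        for i, (a, b) in enumerate(zip(self, self[1:]), start=1):
            if (a.shape[2] != 2 * b.shape[2]) or (a.shape[3] != 2 * b.shape[3]):
                raise ValueError(
                    f"pyramid levels {i} -> {i+1} do not halve: "
                    f"{a.shape} vs {b.shape}")
        for i, f in enumerate(self, start=1):
            if not np.all(np.isfinite(f.data)):
                raise ValueError(f"non-finite values in pyramid level {i}")
        return self


def _to_batched_3ch(image) -> Tensor:
    """Coerce (H,W), (H,W,C), (C,H,W) or (N,C,H,W) input to (N,3,H,W).

    Tensor inputs stay attached to the autograd graph (grayscale is
    replicated with a differentiable concat).
    """
    if isinstance(image, Tensor):
        t = image
        if t.ndim != 4:
            raise ValueError("Tensor input must be batched (N,C,H,W)")
        if t.shape[1] == 1:
            t = concat([t, t, t], axis=1)
        if t.shape[1] != 3:
            raise ValueError(f"expected 1 or 3 channels, got {t.shape[1]}")
        return t
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if arr.shape[-1] in (1, 3) and arr.shape[0] not in (1, 3):
            arr = arr.transpose(2, 0, 1)
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    if arr.shape[1] == 1:
        arr = np.repeat(arr, 3, axis=1)
    if arr.shape[1] != 3:
        raise ValueError(f"expected 1 or 3 channels, got {arr.shape[1]}")
    return Tensor(arr)


class VGGBackbone(Module):
    """Plain 3x3 conv stacks (BN + ReLU), tapped at the five pool outputs."""

    def __init__(self, channels: tuple[int, ...], rng: np.random.Generator,
                 depth: tuple[int, ...] = _VGG_DEPTH):
        super().__init__()
        stages = []
        in_ch = 3
        for c, d in zip(channels, depth):
            layers = []
            for _ in range(d):
                layers.append(ConvBN(in_ch, c, 3, rng, padding=1))
                in_ch = c
            layers.append(MaxPool2d(2))
            stages.append(Sequential(layers))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> FeaturePyramid:
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)


class BasicBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1):
        super().__init__()
        self.c1 = ConvBN(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.c2 = ConvBN(out_ch, out_ch, 3, rng, padding=1, relu=False)
        if stride != 1 or in_ch != out_ch:
            self.short = ConvBN(in_ch, out_ch, 1, rng, stride=stride,
                                relu=False)
        else:
            self.short = Identity()

    def forward(self, x):
        return (self.c2(self.c1(x)) + self.short(x)).relu()


class Res2Block(Module):
    """Hierarchical-residual bottleneck.

    The 1x1 entry projection produces ``scale * width`` mid channels which
    are split into ``scale`` groups; group 1 passes through unchanged
    (unless ``group1_conv``) and group j >= 2 is convolved on the sum of
    itself and the previous group's output, growing the receptive field
    within one block. With ``scale == 1`` the block degenerates to a plain
    1x1 / 3x3 / 1x1 bottleneck. A stride-2 block downsamples the mid
    feature by mean pooling before the split so the hierarchical additions
    stay aligned.
    """

    def __init__(self, in_ch: int, out_ch: int, rng, scale: int = 4,
                 width: int = 26, stride: int = 1, group1_conv: bool = False):
        super().__init__()
        if scale < 1:
            raise ValueError("scale must be >= 1")
        mid = scale * width
        self.scale = scale
        self.width = width
        self.stride = stride
        self.group1_conv = group1_conv
        self.entry = ConvBN(in_ch, mid, 1, rng)
        n_convs = 1 if scale == 1 else (scale if group1_conv else scale - 1)
        self.convs = ModuleList(
            [ConvBN(width, width, 3, rng, padding=1) for _ in range(n_convs)])
        self.exit = ConvBN(mid, out_ch, 1, rng, relu=False)
        if stride != 1 or in_ch != out_ch:
            self.short = ConvBN(in_ch, out_ch, 1, rng, stride=stride,
                                relu=False)
        else:
            self.short = Identity()

    def forward(self, x):
        y = self.entry(x)
        if self.stride != 1:
            y = avg_pool2d(y, self.stride)
        s, w = self.scale, self.width
        groups = [y[:, k * w:(k + 1) * w] for k in range(s)]
        if s == 1:
            outs = [self.convs[0](groups[0])]
        else:
            conv_iter = iter(self.convs)
            if self.group1_conv:
                prev = next(conv_iter)(groups[0])
            else:
                prev = groups[0]
            outs = [prev]
            for xj in groups[1:]:
                prev = next(conv_iter)(xj + prev)
                outs.append(prev)
        y = concat(outs, axis=1) if len(outs) > 1 else outs[0]
        return (self.exit(y) + self.short(x)).relu()


def res2_block(x, scale: int, width: int, seed: int = 0,
               group1_conv: bool = False) -> Tensor:
    """Apply a freshly seeded same-channel hierarchical-residual block."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    rng = np.random.default_rng(seed)
    block = Res2Block(x.shape[1], x.shape[1], rng, scale=scale, width=width,
                      group1_conv=group1_conv).eval()
    return block(x)


class ResidualBackbone(Module):
    """Stem (7x7/2) + max pool + four residual stages."""

    def __init__(self, spec: BackboneSpec, rng: np.random.Generator):
        super().__init__()
        c = spec.channel_counts
        self.stem = ConvBN(3, c[0], 7, rng, stride=2, padding=3)
        self.pool = MaxPool2d(3, 2, 1)
        stages = []
        in_ch = c[0]
        for si, out_ch in enumerate(c[1:]):
            stride = 1 if si == 0 else 2
            blocks = []
            for bi in range(spec.blocks_per_stage):
                bs = stride if bi == 0 else 1
                if spec.variant == "resnet":
                    blocks.append(BasicBlock(in_ch, out_ch, rng, stride=bs))
                else:
                    width = max(1, (out_ch // 4) * spec.res2net_width // 64)
                    blocks.append(Res2Block(
                        in_ch, out_ch, rng, scale=spec.res2net_scale,
                        width=width, stride=bs,
                        group1_conv=spec.group1_conv))
                in_ch = out_ch
            stages.append(Sequential(blocks))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> FeaturePyramid:
        f1 = self.stem(x)
        feats = [f1]
        x = self.pool(f1)
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)


def build_backbone(spec: BackboneSpec, seed: int = 0) -> Module:
    """Build a seeded backbone; optionally load exported weights."""
    rng = np.random.default_rng(seed)
    if spec.variant == "vgg":
        model = VGGBackbone(spec.channel_counts, rng)
    else:
        model = ResidualBackbone(spec, rng)
    if spec.pretrained:
        state = dict(np.load(spec.weights_path))
        model.load_state_dict(state)
    return model


def extract_features(image, spec: BackboneSpec | None = None,
                     seed: int = 0) -> FeaturePyramid:
    """Run a seeded backbone over one image and return the validated pyramid.

    The image spatial size must be divisible by 32 so that all five
    strides land on integer sizes.
    """
    spec = spec or BackboneSpec()
    x = _to_batched_3ch(image)
    H, W = x.shape[2], x.shape[3]
    if H % 32 or W % 32:
        raise ValueError(
            f"input size ({H},{W}) must be divisible by 32 for a "
            "5-level stride-2 pyramid")
    model = build_backbone(spec, seed=seed).eval()
    return model(x).validate()
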