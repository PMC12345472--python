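"""Feature-extraction backbone: residual bottleneck stages with SE recalibration.

The architecture follows the SE-augmented ResNet-50 recipe: a convolutional
stem, four bottleneck stages whose output widths quadruple the internal width,
and squeeze-and-excitation (SE) gates that rescale channels using globally
pooled statistics pushed through a two-layer bottleneck (reduction ratio 16).
Two presets ship: ``fe_net50`` (the full-size network, 224x224 inputs,
2048-d embeddings) and ``fe_net_tiny`` (a stride-compatible reduction for
64x64 inputs and desk-scale training, 256-d embeddings).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import tensor as F


def batch_normalize(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Normalize per feature over the batch axis: ``(x - mu_B)/sqrt(var_B + eps)``.

    ``x`` is (batch, features...); statistics are taken over axis 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 1 or x.size == 0:
        raise ValueError("empty batch")
    if eps <= 0:
        raise ValueError("eps must be positive")
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    return (x - mu) / np.sqrt(var + eps)


@dataclasses.dataclass(frozen=True)
class BackbonePreset:
    name: str
    stage_channels: tuple[int, int, int, int]
    blocks_per_stage: tuple[int, int, int, int]
    se_reduction: int = 16
    se_placement: str = "last_block_per_stage"   # or "every_block"
    input_size: tuple[int, int] = (224, 224)
    embed_dim: int = 2048
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)

    def __post_init__(self):
        if self.embed_dim != self.stage_channels[-1]:
            raise ValueError("embed_dim must equal the last stage width")
        for c in self.stage_channels:
            if c % self.se_reduction:
                raise ValueError("stage channels must be divisible by se_reduction")
        if self.se_placement not in ("last_block_per_stage", "every_block"):
            raise ValueError("unknown se_placement")


PRESETS: dict[str, BackbonePreset] = {
    "fe_net50": BackbonePreset(
        name="fe_net50",
        stage_channels=(256, 512, 1024, 2048),
        blocks_per_stage=(3, 4, 6, 3),
        input_size=(224, 224),
        embed_dim=2048,
    ),
    "fe_net_tiny": BackbonePreset(
        name="fe_net_tiny",
        stage_channels=(32, 64, 128, 256),
        blocks_per_stage=(1, 1, 2, 1),
        input_size=(64, 64),
        embed_dim=256,
        stem_channels=16,
        stem_kernel=3,
        stem_stride=1,
        stage_strides=(2, 2, 2, 2),
    ),
}


class SEBlock(nn.Module):
    """Channel gate ``sigmoid(W2 relu(W1 GAP(F)))`` applied multiplicatively.

    Realized with 1x1-convolution-equivalent dense maps C -> C/r -> C.
    """

    def __init__(self, rng, channels: int, reduction: int):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by reduction")
        self.hidden = channels // reduction
        self.w1 = nn.Parameter(nn.he_init(rng, (channels, self.hidden), self.hidden))
        self.b1 = nn.Parameter(np.zeros(self.hidden))
        self.w2 = nn.Parameter(nn.he_init(rng, (self.hidden, channels), channels))
        self.b2 = nn.Parameter(np.zeros(channels))

    def gate(self, x):
        z = F.global_avg_pool(x)
        z = F.relu(F.matmul(z, self.w1) + self.b1)
        return F.sigmoid(F.matmul(z, self.w2) + self.b2)

    def forward(self, x):
        g = self.gate(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1)


def se_recalibrate(feature_map, se: SEBlock):
    """Apply an SE gate to a feature map (accepts Tensor or ndarray)."""
    x = feature_map if isinstance(feature_map, nn.Tensor) else nn.Tensor(feature_map)
    return se(x)


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 expand with a residual connection."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int,
                 se: SEBlock | None = None):
        super().__init__()
        mid = out_ch // 4
        self.conv1 = nn.Conv2d(rng, in_ch, mid, 1)
        self.bn1 = nn.BatchNorm(mid)
        self.conv2 = nn.Conv2d(rng, mid, mid, 3, stride=stride, pad=1)
        self.bn2 = nn.BatchNorm(mid)
        self.conv3 = nn.Conv2d(rng, mid, out_ch, 1)
        self.bn3 = nn.BatchNorm(out_ch, zero_init=True)
        self.se = se
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(rng, in_ch, out_ch, 1, stride=stride)
            self.proj_bn = nn.BatchNorm(out_ch)
        else:
            self.proj = None

    def forward(self, x):
        out = F.relu(self.bn1(self.conv1(x)))
        out = F.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        if self.se is not None:
            out = self.se(out)
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return F.relu(out + skip)


class Backbone(nn.Module):
    """Stem + four SE-recalibrated bottleneck stages + global average pool."""

    def __init__(self, preset: BackbonePreset, seed: int = 0):
        super().__init__()
        self.preset = preset
        rng = np.random.default_rng(seed)
        k, s = preset.stem_kernel, preset.stem_stride
        self.stem_conv = nn.Conv2d(rng, 3, preset.stem_channels, k,
                                   stride=s, pad=k // 2)
        self.stem_bn = nn.BatchNorm(preset.stem_channels)
        self.pool_k = 3 if preset.stem_kernel == 7 else 2
        self.pool_pad = 1 if self.pool_k == 3 else 0
        self.stages = []
        in_ch = preset.stem_channels
        for out_ch, n_blocks, stride in zip(preset.stage_channels,
                                            preset.blocks_per_stage,
                                            preset.stage_strides):
            blocks = []
            for b in range(n_blocks):
                want_se = (preset.se_placement == "every_block"
                           or b == n_blocks - 1)
                se = SEBlock(rng, out_ch, preset.se_reduction) if want_se else None
                blocks.append(Bottleneck(rng, in_ch, out_ch,
                                         stride if b == 0 else 1, se))
                in_ch = out_ch
            self.stages.append(nn.Sequential(*blocks))

    def forward(self, x):
        """Return (feature map F, pooled embedding x)."""
        x = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        h, w = self.preset.input_size
        if x.shape[2:] != (h, w):
            raise ValueError(f"expected {h}x{w} input, got {x.shape[2:]}")
        out = F.relu(self.stem_bn(self.stem_conv(x)))
        out = F.max_pool2d(out, self.pool_k, 2, self.pool_pad)
        for stage in self.stages:
            out = stage(out)
        return out, F.global_avg_pool(out)


def build_backbone(preset: str | BackbonePreset, seed: int = 0) -> Backbone:
    """Instantiate a backbone with deterministic seed-driven initialization."""
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset: {preset}") from None
    return Backbone(preset, seed=seed)


def forward_features(batch: np.ndarray, backbone: Backbone):
    """Run the backbone; returns (F, x) with ``x`` = GAP(F)."""
    return backbone(batch)
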