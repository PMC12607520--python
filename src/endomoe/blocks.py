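"""Building blocks of the routed mixture-of-experts classifier.

Every block operates on (N, C, H, W) float tensors.  The expert block
composes, in order:

1. a spatial-channel attention unit — a 7x7 conv producing a single-channel
   spatial gate (sigmoid of a batch-normed conv response) and a squeeze-style
   per-channel gate (global average pool -> 1x1 bottleneck with reduction
   ratio -> sigmoid), both multiplied elementwise into the input;
2. a three-layer conv stack — 1x1 compression to a 32-channel bottleneck,
   a 3x3 grouped conv (4 groups), and 1x1 restoration to the input width;
3. squeeze-and-excitation recalibration of the conv-stack output;
4. a residual connection from the block input, with ReLU applied after the
   sum.

Note on naming: the per-pixel H x W gate is called *spatial* here and the
per-channel vector *channel*, after what each gate modulates.  Some
descriptions of this architecture label the 7x7-conv stream "channel
attention" and the pooled bottleneck stream "spatial attention"; the
computations are the ones implemented below either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, ConfigurationError, Conv2d, Module


@dataclass
class BlockConfig:
    """Hyperparameters of one expert block.

    ``attn_reduction`` and ``se_reduction`` are the channel-compression
    factors of the attention and squeeze-excitation bottlenecks;
    ``bottleneck_channels`` / ``conv_groups`` shape the grouped conv stack.
    ``use_scab`` / ``use_se`` are the ablation switches: off means the
    corresponding sub-computation is the identity.
    """

    in_channels: int
    bottleneck_channels: int = 32
    conv_groups: int = 4
    se_reduction: int = 16
    attn_reduction: int = 16
    use_se: bool = True
    use_scab: bool = True

    def validate(self) -> None:
        if self.use_scab and self.in_channels % self.attn_reduction:
            raise ConfigurationError(
                f"in_channels={self.in_channels} not divisible by "
                f"attn_reduction={self.attn_reduction}"
            )
        if self.use_se and self.in_channels % self.se_reduction:
            raise ConfigurationError(
                f"in_channels={self.in_channels} not divisible by "
                f"se_reduction={self.se_reduction}"
            )
        if self.bottleneck_channels % self.conv_groups:
            raise ConfigurationError(
                f"bottleneck_channels={self.bottleneck_channels} not divisible "
                f"by conv_groups={self.conv_groups}"
            )


@dataclass
class AttentionMaps:
    """Gates captured from one attention unit (plain arrays, detached).

    ``spatial_gate``: (N, H, W) in (0,1); ``channel_gate``: (N, C) in (0,1).
    """

    spatial_gate: np.ndarray
    channel_gate: np.ndarray


class Stem(Module):
    """Low-level feature extractor: 7x7/2 conv (64 filters) -> BN -> ReLU ->
    3x3/2 max pool, all with 'same' padding, so 224x224x3 maps to 56x56x64."""

    def __init__(self, rng: np.random.Generator, in_channels: int = 3,
                 out_channels: int = 64):
        super().__init__()
        self.in_channels = in_channels
        self.conv = Conv2d(in_channels, out_channels, 7, rng, stride=2, bias=False)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"stem expects {self.in_channels}-channel input, "
                f"received {x.shape[1]}"
            )
        return ag.max_pool2d(ag.relu(self.bn(self.conv(x))), 3, 2, "same")

    __call__ = forward


class ChannelGate(Module):
    """Pooled-bottleneck channel gate: GAP -> 1x1 (C -> C/r) -> ReLU ->
    1x1 (C/r -> C) -> sigmoid.  Used for the attention channel stream,
    squeeze-and-excitation, and the global context block (identical math,
    independent weights).  Bottleneck convs carry no bias."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"channels={channels} not divisible by reduction={reduction}"
            )
        hidden = channels // reduction
        self.squeeze = Conv2d(channels, hidden, 1, rng, bias=False)
        self.excite = Conv2d(hidden, channels, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        pooled = ag.global_avg_pool(x)  # (N, C, 1, 1)
        return ag.sigmoid(self.excite(ag.relu(self.squeeze(pooled))))

    __call__ = forward


class SpatialChannelAttention(Module):
    """Dual-gate attention: a 7x7-conv spatial gate and a pooled channel gate,
    both sigmoid-scaled into (0,1) and multiplied into the input."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.spatial_conv = Conv2d(cfg.in_channels, 1, 7, rng, bias=False)
        self.spatial_bn = BatchNorm2d(1)
        self.channel = ChannelGate(cfg.in_channels, cfg.attn_reduction, rng)

    def forward(self, z: Tensor) -> tuple[AttentionMaps, Tensor]:
        sg = ag.sigmoid(self.spatial_bn(self.spatial_conv(z)))  # (N,1,H,W)
        cg = self.channel(z)  # (N,C,1,1)
        maps = AttentionMaps(
            spatial_gate=sg.data[:, 0].copy(),
            channel_gate=cg.data[:, :, 0, 0].copy(),
        )
        return maps, z * sg * cg

    __call__ = forward


class ExpertConvStack(Module):
    """1x1 compress -> 3x3 grouped conv -> 1x1 restore, BN after each conv,
    ReLU after the first two; the restoring conv is left pre-activation so the
    residual sum decides the sign."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        b = cfg.bottleneck_channels
        self.conv1 = Conv2d(cfg.in_channels, b, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(b)
        self.conv2 = Conv2d(b, b, 3, rng, groups=cfg.conv_groups, bias=False)
        self.bn2 = BatchNorm2d(b)
        self.conv3 = Conv2d(b, cfg.in_channels, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(cfg.in_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.bn1(self.conv1(x)))
        x = ag.relu(self.bn2(self.conv2(x)))
        return self.bn3(self.conv3(x))

    __call__ = forward


class SqueezeExcite(ChannelGate):
    """Channel recalibration gate for the conv-stack output."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        cfg.validate()
        super().__init__(cfg.in_channels, cfg.se_reduction, rng)


class GlobalContext(ChannelGate):
    """Whole-map channel gate applied before the final classifier head."""


class ExpertBlock(Module):
    """One expert: attention -> conv stack -> SE gate -> residual -> ReLU.

    Ablations: ``use_scab=False`` makes the attention stage the identity;
    ``use_se=False`` fixes the SE gate at 1.  The attention maps of the last
    forward pass are kept on ``last_attention`` for diagnostics.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        if cfg.use_scab:
            self.attention = SpatialChannelAttention(cfg, rng)
        if cfg.use_se:
            self.se = SqueezeExcite(cfg, rng)
        self.stack = ExpertConvStack(cfg, rng)
        self.last_attention: AttentionMaps | None = None

    def forward(self, z_in: Tensor) -> Tensor:
        if z_in.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"expert block expects {self.cfg.in_channels} channels, "
                f"received {z_in.shape[1]}"
            )
        if self.cfg.use_scab:
            self.last_attention, zf = self.attention(z_in)
        else:
            self.last_attention, zf = None, z_in
        x3 = self.stack(zf)
        if self.cfg.use_se:
            x3 = x3 * self.se(x3)
        out = ag.relu(x3 + z_in)
        if out.shape != z_in.shape:  # pragma: no cover - config bug guard
            raise RuntimeError("residual/main path shape mismatch")
        return out

    __call__ = forward


class Transition(Module):
    """Between-stage compression: 1x1 conv -> BN -> ReLU -> 2x2/2 average
    pool.  Halves H and W (floor for odd sizes) and sets the channel count."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 1, rng, bias=False)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.avg_pool2d(ag.relu(self.bn(self.conv(x))), 2)

    __call__ = forward
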