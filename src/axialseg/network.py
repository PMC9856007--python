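"""The axial-attention segmentation network (AABTS-Net).

A 3-D U-shaped encoder-decoder. The encoder stacks basic convolutional blocks
(two 3x3x3 convolutions, each followed by Leaky ReLU with slope 0.01) and
halves resolution with stride-2 convolutions, doubling the filter count from
32 up to a cap of 320; for a 128-cube patch the coarsest feature is 4x4x4.
The decoder mirrors this with 2x transposed convolutions. Skip connections at
the sub-full-resolution levels are fused by the axial attention mechanism;
the full-resolution skip (where attention would be prohibitively large) uses
plain concatenation. The final 1x1x1 convolution with a sigmoid produces
three independent probability channels (ET, TC, WT); three auxiliary sigmoid
heads at the middle decoder levels provide deep supervision.

Instance normalisation is inserted after each convolution by default: 3-D
segmentation at batch size 2 is numerically fragile without some
normalisation. It can be disabled via ``NetworkConfig.instance_norm``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import grad
from .attention import AxialAttentionFusion, head_schedule
from .grad import Tensor
from .nn import (Conv3d, ConvTranspose3d2x, InstanceNorm3d, LeakyReLU, Module,
                 Sequential, Sigmoid)


@dataclasses.dataclass
class NetworkConfig:
    in_channels: int = 4
    out_channels: int = 3
    base_filters: int = 32
    max_filters: int = 320
    levels: int = 6
    patch_size: tuple[int, int, int] = (128, 128, 128)
    lrelu_slope: float = 0.01
    #: skip levels carrying axial attention; None = all sub-full-resolution skips
    aam_levels: tuple[int, ...] | None = None
    #: decoder levels with auxiliary sigmoid heads; None = middle three
    ds_head_levels: tuple[int, ...] | None = None
    attention_base: tuple[int, int] = (4, 16)   # (heads, head_dim) at shallowest AAM
    instance_norm: bool = True
    aam_residual: bool = True
    aam_embed_per_axis: bool = True
    aam_axis_order: tuple[str, ...] = ("depth", "height", "width")

    def __post_init__(self):
        down = 2 ** (self.levels - 1)
        if any(p % down for p in self.patch_size):
            raise ValueError(
                f"patch size {self.patch_size} must be divisible by 2^(levels-1) = {down}")
        if self.aam_levels is None:
            # every skip level except full resolution: exactly the four
            # coarsest for the 6-level default
            self.aam_levels = tuple(range(1, self.levels - 1))
        if self.ds_head_levels is None:
            self.ds_head_levels = tuple(range(1, min(4, self.levels - 1)))
        bad = [l for l in self.aam_levels if not 1 <= l <= self.levels - 2]
        if bad:
            raise ValueError(f"aam_levels {bad} outside the skip range 1..{self.levels - 2}")


def channels_at_level(level: int, config: NetworkConfig) -> int:
    """Filter count: doubles per level from base_filters, capped at max_filters."""
    if not 0 <= level < config.levels:
        raise ValueError(f"level {level} outside 0..{config.levels - 1}")
    return min(config.base_filters * 2 ** level, config.max_filters)


def level_extent(level: int, config: NetworkConfig) -> tuple[int, int, int]:
    return tuple(p // 2 ** level for p in config.patch_size)


class ConvBlock(Module):
    """Two 3x3x3 convolutions, each followed by (instance norm and) LReLU."""

    def __init__(self, in_ch: int, out_ch: int, cfg: NetworkConfig, rng):
        layers = []
        for i, (ci, co) in enumerate([(in_ch, out_ch), (out_ch, out_ch)]):
            layers.append(Conv3d(ci, co, kernel=3, rng=rng))
            if cfg.instance_norm:
                layers.append(InstanceNorm3d(co))
            layers.append(LeakyReLU(cfg.lrelu_slope))
        self.block = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class _Down(Module):
    """Stride-2 convolution performing the resolution halving and channel increase."""

    def __init__(self, in_ch: int, out_ch: int, cfg: NetworkConfig, rng):
        layers = [Conv3d(in_ch, out_ch, kernel=3, stride=2, rng=rng)]
        if cfg.instance_norm:
            layers.append(InstanceNorm3d(out_ch))
        layers.append(LeakyReLU(cfg.lrelu_slope))
        self.block = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class _Head(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        self.conv = Conv3d(in_ch, out_ch, kernel=1, rng=rng)
        self.act = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.conv(x))


class AABTSNet(Module):
    """Encoder-decoder with AAM skip fusion and deep supervision."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [channels_at_level(l, config) for l in range(config.levels)]

        self.enc_blocks = [ConvBlock(config.in_channels if l == 0 else ch[l], ch[l], config, rng)
                           for l in range(config.levels)]
        self.downs = [_Down(ch[l], ch[l + 1], config, rng)
                      for l in range(config.levels - 1)]

        self.aam = {}
        self.ups = {}
        self.dec_blocks = []
        for l in range(config.levels - 2, -1, -1):
            if l in config.aam_levels:
                heads, hdim = head_schedule(l, config.aam_levels, config.attention_base)
                self.aam[l] = AxialAttentionFusion(
                    ch[l], ch[l + 1], level_extent(l, config), heads, hdim, rng=rng,
                    axis_order=config.aam_axis_order,
                    embed_per_axis=config.aam_embed_per_axis,
                    use_residual=config.aam_residual)
                in_ch = ch[l]
            else:
                self.ups[l] = ConvTranspose3d2x(ch[l + 1], ch[l], rng=rng)
                in_ch = 2 * ch[l]
            self.dec_blocks.append(ConvBlock(in_ch, ch[l], config, rng))
        # dec_blocks[i] serves level (levels-2-i)
        self.main_head = _Head(ch[0], config.out_channels, rng)
        self.aux_heads = {l: _Head(ch[l], config.out_channels, rng)
                          for l in config.ds_head_levels}

    # attribute discovery for dicts of modules
    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for name, table in (("aam", self.aam), ("ups", self.ups), ("aux_heads", self.aux_heads)):
            for key, mod in sorted(table.items()):
                yield from mod.named_parameters(f"{prefix}{name}.{key}.")

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Return the full-resolution sigmoid map and the auxiliary maps
        (at their native resolutions, ordered fine -> coarse)."""
        cfg = self.config
        if x.shape[1] != cfg.in_channels or x.shape[2:] != tuple(cfg.patch_size):
            raise ValueError(
                f"expected input (N, {cfg.in_channels}, {cfg.patch_size}), got {x.shape}")
        skips = []
        cur = x
        for l in range(cfg.levels):
            cur = self.enc_blocks[l](cur)
            if l < cfg.levels - 1:
                skips.append(cur)
                cur = self.downs[l](cur)

        aux: list[tuple[int, Tensor]] = []
        for i, l in enumerate(range(cfg.levels - 2, -1, -1)):
            if l in self.aam:
                cur = self.aam[l](skips[l], cur)
            else:
                up = self.ups[l](cur)
                cur = grad.concat([up, skips[l]], axis=1)
            cur = self.dec_blocks[i](cur)
            if l in self.aux_heads:
                aux.append((l, self.aux_heads[l](cur)))
        main = self.main_head(cur)
        aux_sorted = [t for _, t in sorted(aux, key=lambda p: p[0])]
        return main, aux_sorted

    def summary(self) -> dict:
        """Per-level channel/extent schedule and parameter count, computed
        from the configuration (no forward pass)."""
        cfg = self.config
        levels = [{"level": l,
                   "channels": channels_at_level(l, cfg),
                   "extent": list(level_extent(l, cfg)),
                   "aam": l in cfg.aam_levels,
                   "aux_head": l in cfg.ds_head_levels}
                  for l in range(cfg.levels)]
        return {"input_channels": cfg.in_channels,
                "output_channels": cfg.out_channels,
                "patch_size": list(cfg.patch_size),
                "levels": levels,
                "num_parameters": self.num_parameters()}


def build_model(config: NetworkConfig, seed: int = 0) -> AABTSNet:
    return AABTSNet(config, seed=seed)
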