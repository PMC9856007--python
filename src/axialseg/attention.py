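"""Axial attention mechanism (AAM) for skip-connection fusion.

Full 3-D self-attention over a D×H×W feature map costs an attention matrix of
(DHW)² entries. Axial attention factorises it: multi-head self-attention is
applied to every 1-D line of voxels along one axis at a time, sequentially
over depth, height, and width, reducing the per-line matrix to L² entries
(L the axis extent). The fusion block receives the skip feature F_sc and the
coarser decoder feature F_pre; F_pre is upsampled by a transposed convolution
to F, position-embedded, passed through the three axis attentions
(F -> F_saD -> F_saDH -> F_saDHW), and combined residually:

    F_att = F_saDHW + F
    F_out = F_att + F_sc

Per axis, q and k are learned linear maps to a reduced dimension
C_hat = heads x head_dim, v keeps the full C channels (partitioned across
heads), the correlation is a plain inner product (no temperature), rows are
softmax-normalised, and a final linear map restores the channel space.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import grad
from .grad import Tensor
from .nn import ConvTranspose3d2x, Linear, Module, Parameter

AXES = ("depth", "height", "width")
_AXIS_INDEX = {"depth": 2, "height": 3, "width": 4}


@dataclasses.dataclass
class FeatureMap:
    """Activation tensor (C, D, H, W) or (N, C, D, H, W) tagged with its
    resolution level (0 = full resolution)."""

    data: Tensor
    level: int

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("resolution level must be >= 0")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate feature extents {self.data.shape}")


def head_schedule(level: int, aam_levels: tuple[int, ...],
                  base: tuple[int, int] = (4, 16)) -> tuple[int, int]:
    """(heads, head_dim) for an AAM level: (4, 16) at the shallowest AAM level,
    both doubled at each coarser level."""
    levels = sorted(aam_levels)
    if level not in levels:
        raise ValueError(f"level {level} carries no axial attention (AAM levels {levels})")
    k = levels.index(level)
    return base[0] * 2 ** k, base[1] * 2 ** k


def attention_matrix_elements(shape: tuple[int, int, int]) -> dict[str, int]:
    """Attention-matrix element counts for one pass over a D×H×W feature map.

    Axial: each axis forms one L×L matrix per line, with as many lines as the
    orthogonal plane has voxels. Dense 3-D self-attention forms one
    (DHW)×(DHW) matrix. The ratio is the complexity reduction that motivates
    factorising the attention.
    """
    d, h, w = shape
    axial = d * d * (h * w) + h * h * (d * w) + w * w * (d * h)
    return {"axial": axial, "dense": (d * h * w) ** 2}


class AxisSelfAttention(Module):
    """Multi-head self-attention along one axis of a (N, C, D, H, W) tensor.

    Every line parallel to the axis attends within itself only; positions on
    other axes index independent lines. The additive position embedding (one
    learned C-vector per position along the axis) is applied first.
    """

    def __init__(self, channels: int, axis: str, length: int, heads: int,
                 head_dim: int, rng: np.random.Generator | None = None,
                 use_position_embedding: bool = True):
        rng = rng or np.random.default_rng()
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if channels % heads != 0:
            raise ValueError(f"channels ({channels}) must divide across heads ({heads})")
        self.axis = axis
        self.heads = heads
        self.head_dim = head_dim
        self.channels = channels
        reduced = heads * head_dim
        self.q_proj = Linear(channels, reduced, bias=False, rng=rng)
        self.k_proj = Linear(channels, reduced, bias=False, rng=rng)
        self.v_proj = Linear(channels, channels, bias=False, rng=rng)
        self.out_proj = Linear(channels, channels, rng=rng)
        if use_position_embedding:
            self.pos_embed = Parameter(
                rng.normal(0.0, 0.02, size=(channels, length)).astype(np.float32))
        else:
            self.pos_embed = None

    def add_position(self, x: Tensor) -> Tensor:
        """Broadcast-add the per-position embedding along this attention's axis."""
        if self.pos_embed is None:
            return x
        ax = _AXIS_INDEX[self.axis]
        shape = [1, self.channels, 1, 1, 1]
        shape[ax] = self.pos_embed.shape[1]
        return x + grad.reshape(self.pos_embed, tuple(shape))

    def forward(self, x: Tensor, embed_position: bool = True) -> Tensor:
        n, c, d, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if embed_position:
            x = self.add_position(x)
        ax = _AXIS_INDEX[self.axis]
        length = x.shape[ax]
        # lines along `ax` become sequences: (batch_of_lines, L, C)
        order = [0] + [a for a in (2, 3, 4) if a != ax] + [ax, 1]
        seq = grad.reshape(grad.transpose(x, order), (-1, length, c))

        q = self.q_proj(seq)   # (B, L, heads*head_dim)
        k = self.k_proj(seq)
        v = self.v_proj(seq)   # (B, L, C)
        b = seq.shape[0]

        def split(t: Tensor, dim: int) -> Tensor:
            t = grad.reshape(t, (b, length, self.heads, dim))
            return grad.transpose(t, (0, 2, 1, 3))  # (B, heads, L, dim)

        qh, kh = split(q, self.head_dim), split(k, self.head_dim)
        vh = split(v, c // self.heads)
        # delta[j, i] = q(f_i) . k(f_j); rows j softmax-normalised over i
        delta = kh @ grad.transpose(qh, (0, 1, 3, 2))          # (B, heads, L, L)
        attn = grad.softmax(delta, axis=-1)
        out = attn @ vh                                         # (B, heads, L, C/heads)
        out = grad.reshape(grad.transpose(out, (0, 2, 1, 3)), (b, length, c))
        out = self.out_proj(out)

        # back to (N, C, D, H, W)
        spatial = [x.shape[a] for a in (2, 3, 4) if a != ax]
        out = grad.reshape(out, (n, *spatial, length, c))
        inv = np.argsort(order)
        return grad.transpose(out, tuple(inv))

    def attention_matrix(self, x: Tensor) -> np.ndarray:
        """Row-stochastic attention matrices, shape (lines, heads, L, L).
        Diagnostic path sharing the forward's projections."""
        with grad.no_grad():
            xp = self.add_position(x)
            ax = _AXIS_INDEX[self.axis]
            length = xp.shape[ax]
            order = [0] + [a for a in (2, 3, 4) if a != ax] + [ax, 1]
            seq = grad.reshape(grad.transpose(xp, order), (-1, length, self.channels))
            q, k = self.q_proj(seq), self.k_proj(seq)
            b = seq.shape[0]
            qh = grad.transpose(grad.reshape(q, (b, length, self.heads, self.head_dim)),
                                (0, 2, 1, 3))
            kh = grad.transpose(grad.reshape(k, (b, length, self.heads, self.head_dim)),
                                (0, 2, 1, 3))
            attn = grad.softmax(kh @ grad.transpose(qh, (0, 1, 3, 2)), axis=-1)
        return attn.data


class AxialAttentionFusion(Module):
    """The AAM skip-fusion block: upsample, position-embed, attend over the
    three axes in sequence, and add the two residual paths."""

    def __init__(self, skip_channels: int, pre_channels: int,
                 spatial_shape: tuple[int, int, int], heads: int, head_dim: int,
                 rng: np.random.Generator | None = None,
                 axis_order: tuple[str, ...] = AXES,
                 embed_per_axis: bool = True,
                 use_residual: bool = True):
        rng = rng or np.random.default_rng()
        if sorted(axis_order) != sorted(AXES):
            raise ValueError(f"axis_order must permute {AXES}")
        self.axis_order = tuple(axis_order)
        self.embed_per_axis = embed_per_axis
        self.use_residual = use_residual
        self.upsample = ConvTranspose3d2x(pre_channels, skip_channels, rng=rng)
        lengths = dict(zip(AXES, spatial_shape))
        self.attentions = [
            AxisSelfAttention(skip_channels, axis, lengths[axis], heads, head_dim,
                              rng=rng,
                              use_position_embedding=embed_per_axis or i == 0)
            for i, axis in enumerate(self.axis_order)
        ]

    def upsample_previous(self, f_pre: FeatureMap) -> FeatureMap:
        """Transposed convolution doubling every spatial extent of the coarser
        decoder feature and matching the skip channel count."""
        out = self.upsample(f_pre.data)
        return FeatureMap(out, level=f_pre.level - 1)

    def forward(self, f_sc: Tensor, f_pre: Tensor) -> Tensor:
        expected = tuple(2 * s for s in f_pre.shape[2:])
        if f_sc.shape[2:] != expected:
            raise ValueError(
                f"skip shape {f_sc.shape[2:]} is not double the coarser shape {f_pre.shape[2:]}")
        f = self.upsample(f_pre)
        if f.shape != f_sc.shape:
            raise ValueError(f"fused shape {f.shape} != skip shape {f_sc.shape}")
        cur = f
        for i, attn in enumerate(self.attentions):
            cur = attn(cur, embed_position=self.embed_per_axis or i == 0)
        f_att = cur + f if self.use_residual else cur
        return f_att + f_sc

    def aam_forward(self, f_sc: FeatureMap, f_pre: FeatureMap) -> FeatureMap:
        if f_pre.level != f_sc.level + 1:
            raise ValueError(
                f"previous feature must be one level coarser: got skip level {f_sc.level}, "
                f"previous level {f_pre.level}")
        return FeatureMap(self.forward(f_sc.data, f_pre.data), level=f_sc.level)
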