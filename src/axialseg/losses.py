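"""Hybrid training loss: batch-pooled Dice + weighted binary cross-entropy,
with exponentially decaying deep-supervision weights.

The Dice term is *batch-based*: the sums run jointly over batch, region
channels and voxels, treating the whole mini-batch as one pooled sample.
A per-sample Dice explodes in gradient on tumor-free samples (denominator
near zero); pooling keeps the denominator dominated by whichever samples do
contain tumor, which is the stability argument for this form.

    L_Dice = 1 - (2 * sum(y_p * y_t) + eps) / (sum(y_p) + sum(y_t) + eps)
    L_BCE  = mean( -lambda * y_t * log(y_p) - (1 - y_t) * log(1 - y_p) )
    L_total = L_H1 + alpha * L_H2 + beta * L_H3 + gamma * L_H4

with (alpha, beta, gamma) = (0.5, 0.25, 0.125): the finer the auxiliary
head's resolution, the larger its weight. Auxiliary outputs are upsampled to
full resolution before their loss is computed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence


from . import grad
from .grad import Tensor


@dataclasses.dataclass
class LossConfig:
    lambda_bce: float = 1.0
    ds_weights: tuple[float, ...] = (0.5, 0.25, 0.125)
    smooth: float = 1e-5
    clip_eps: float = 1e-7

    def __post_init__(self):
        if self.lambda_bce <= 0 or self.smooth <= 0:
            raise ValueError("lambda_bce and smooth must be positive")
        if any(a <= b for a, b in zip(self.ds_weights, self.ds_weights[1:])):
            raise ValueError("deep-supervision weights must be strictly decreasing")


def _pair(y_p, y_t) -> tuple[Tensor, Tensor]:
    y_p = grad.as_tensor(y_p)
    y_t = grad.as_tensor(y_t)
    if y_p.shape != y_t.shape:
        raise ValueError(f"prediction shape {y_p.shape} != target shape {y_t.shape}")
    return y_p, y_t


def batch_dice_loss(y_p, y_t, smooth: float = 1e-5) -> Tensor:
    """Soft Dice loss pooled over batch, channels and voxels jointly."""
    y_p, y_t = _pair(y_p, y_t)
    inter = (y_p * y_t).sum()
    denom = y_p.sum() + y_t.sum()
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def bce_loss(y_p, y_t, lambda_bce: float = 1.0, clip_eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy with positive-class weight lambda, averaged over
    every voxel, channel and sample."""
    y_p, y_t = _pair(y_p, y_t)
    p = grad.clip(y_p, clip_eps, 1.0 - clip_eps)
    term = -lambda_bce * y_t * grad.log(p) - (1.0 - y_t) * grad.log(1.0 - p)
    return term.mean()


def head_loss(y_p, y_t, config: LossConfig) -> Tensor:
    return (batch_dice_loss(y_p, y_t, config.smooth)
            + bce_loss(y_p, y_t, config.lambda_bce, config.clip_eps))


def hybrid_total_loss(main_out, aux_outs: Sequence, y_t, config: LossConfig | None = None
                      ) -> Tensor:
    """Deep-supervised total: main head plus down-weighted auxiliary heads.

    ``aux_outs`` are ordered fine -> coarse at their native resolutions and
    are nearest-neighbour-upsampled to the main resolution before their
    Dice+BCE is computed. With the default three heads the weights are
    (0.5, 0.25, 0.125); scaled-down configurations with fewer heads use the
    leading weights.
    """
    config = config or LossConfig()
    if len(aux_outs) > len(config.ds_weights):
        raise ValueError(
            f"{len(aux_outs)} auxiliary heads but only {len(config.ds_weights)} weights")
    main_out = grad.as_tensor(main_out)
    y_t = grad.as_tensor(y_t)
    total = head_loss(main_out, y_t, config)
    full = main_out.shape[-3:]
    for w, aux in zip(config.ds_weights, aux_outs):
        aux = grad.as_tensor(aux)
        factor = full[0] // aux.shape[-3]
        if any(a * factor != f for a, f in zip(aux.shape[-3:], full)):
            raise ValueError(
                f"auxiliary extent {aux.shape[-3:]} does not divide main extent {full}")
        if factor > 1:
            aux = grad.upsample_nearest(aux, factor)
        total = total + w * head_loss(aux, y_t, config)
    return total
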