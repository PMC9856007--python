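"""Training-time data augmentation.

Five stochastic transforms, each drawn independently with probability 0.3 per
case: random rotation, random scaling (factors in (0.65, 1.6), one factor per
axis), elastic deformation, gamma augmentation, and brightness scaling.
Spatial transforms act identically on intensity channels (trilinear) and
region masks (nearest neighbour, so masks stay binary and nested); intensity
transforms touch only the modality channels. All outputs are resampled onto
the original grid, so shapes never change.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import MultiModalVolume, RegionMask, StructureError


@dataclasses.dataclass
class AugmentConfig:
    p_apply: float = 0.3
    rotation_range: float = 15.0          # degrees, per axis
    scale_range: tuple[float, float] = (0.65, 1.6)
    scale_per_axis: bool = True
    elastic_sigma: float = 8.0            # smoothing of the displacement field, voxels
    elastic_alpha: float = 3.0            # displacement standard deviation, voxels
    gamma_range: tuple[float, float] = (0.7, 1.5)
    brightness_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must lie in [0, 1]")
        if self.scale_range[0] >= self.scale_range[1]:
            raise ValueError("scale_range must be (low, high) with low < high")
        if self.gamma_range[0] <= 0:
            raise ValueError("gamma range must be positive")


def sample_scale(rng: np.random.Generator, config: AugmentConfig) -> np.ndarray:
    """Uniform scale factors: three independent draws, or one shared draw."""
    lo, hi = config.scale_range
    if config.scale_per_axis:
        return rng.uniform(lo, hi, size=3)
    return np.full(3, rng.uniform(lo, hi))


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _affine_all(intens: np.ndarray, masks: np.ndarray, matrix: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one linear map about the volume center to every channel."""
    center = (np.asarray(intens.shape[1:]) - 1) / 2.0
    offset = center - matrix @ center
    out_i = np.stack([
        ndimage.affine_transform(c, matrix, offset=offset, order=1, mode="constant", cval=0.0)
        for c in intens])
    out_m = np.stack([
        ndimage.affine_transform(c, matrix, offset=offset, order=0, mode="constant", cval=0)
        for c in masks])
    return out_i.astype(np.float32), out_m.astype(np.uint8)


def _elastic_coords(shape: tuple[int, ...], rng: np.random.Generator,
                    sigma: float, alpha: float) -> np.ndarray:
    disp = []
    for _ in range(3):
        field = rng.uniform(-1, 1, size=shape)
        field = ndimage.gaussian_filter(field, sigma, mode="constant")
        sd = field.std()
        if sd > 0:
            field = field / sd * alpha
        disp.append(field)
    grid = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return np.stack([g + d for g, d in zip(grid, disp)])


def augment_case(vol: MultiModalVolume, regions: RegionMask,
                 rng: np.random.Generator, config: AugmentConfig
                 ) -> tuple[MultiModalVolume, RegionMask]:
    """Apply the five transforms, each with probability ``config.p_apply``.

    Deterministic given the generator state: decisions and parameters are
    drawn in a fixed order.
    """
    if vol.shape != regions.shape:
        raise StructureError(f"volume shape {vol.shape} != region shape {regions.shape}")
    intens = vol.data.astype(np.float32).copy()
    masks = regions.data.copy()
    p = config.p_apply

    if rng.random() < p:  # rotation
        angles = rng.uniform(-config.rotation_range, config.rotation_range, size=3)
        intens, masks = _affine_all(intens, masks, _rotation_matrix(angles))

    if rng.random() < p:  # scaling; factor > 1 enlarges the object
        factors = sample_scale(rng, config)
        intens, masks = _affine_all(intens, masks, np.diag(1.0 / factors))

    if rng.random() < p:  # elastic deformation
        coords = _elastic_coords(intens.shape[1:], rng, config.elastic_sigma,
                                 config.elastic_alpha)
        intens = np.stack([
            ndimage.map_coordinates(c, coords, order=1, mode="constant", cval=0.0)
            for c in intens]).astype(np.float32)
        masks = np.stack([
            ndimage.map_coordinates(c, coords, order=0, mode="constant", cval=0)
            for c in masks]).astype(np.uint8)

    if rng.random() < p:  # gamma on the channel's min-max normalised range
        gamma = rng.uniform(*config.gamma_range)
        for ch in range(intens.shape[0]):
            lo, hi = intens[ch].min(), intens[ch].max()
            if hi > lo:
                unit = (intens[ch] - lo) / (hi - lo)
                intens[ch] = unit ** gamma * (hi - lo) + lo

    if rng.random() < p:  # multiplicative brightness
        intens *= rng.uniform(*config.brightness_range)

    return MultiModalVolume(intens, spacing=vol.spacing), RegionMask(masks)
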