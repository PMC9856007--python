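"""Preprocessing: minimal nonzero crop, conditional z-score, patch fitting.

The pipeline mirrors common practice for skull-stripped MRI: (1) crop each
case to the minimal 3-D bounding box of nonzero intensity across channels;
(2) z-score each channel, restricting the statistics to nonzero voxels when
the crop removed more than a quarter of the volume (small heads on large
grids would otherwise have their statistics dominated by background that the
crop failed to remove); (3) center-crop / zero-pad to the network patch size,
recording the inverse map so predictions can be placed back into the
original geometry.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import LabelVolume, MultiModalVolume, StructureError


class EmptyVolumeError(ValueError):
    """All voxels are zero; no bounding box exists."""


class DegenerateInputError(ValueError):
    """A channel has zero variance in the normalisation region."""


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Per-axis half-open [start, stop) voxel intervals, 0-based."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self):
        if any(a >= b for a, b in zip(self.start, self.stop)):
            raise StructureError(f"degenerate bounding box {self.start}..{self.stop}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))


@dataclasses.dataclass(frozen=True)
class NormStats:
    mu: float
    sigma: float
    region: str  # "all" or "nonzero"


@dataclasses.dataclass(frozen=True)
class FitInfo:
    """Inverse map of :func:`fit_to_patch` (per-axis crop offset and padding)."""

    original_shape: tuple[int, int, int]
    crop_start: tuple[int, int, int]
    pad_before: tuple[int, int, int]


def nonzero_bbox(vol: MultiModalVolume) -> BoundingBox:
    """Tightest box containing every voxel nonzero in any channel."""
    nz = np.any(vol.data != 0, axis=0)
    if not nz.any():
        raise EmptyVolumeError("volume is identically zero; no nonzero bounding box")
    start, stop = [], []
    for axis in range(3):
        proj = np.any(nz, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        start.append(int(idx[0]))
        stop.append(int(idx[-1] + 1))
    return BoundingBox(tuple(start), tuple(stop))


def crop_to_bbox(vol: MultiModalVolume, labels: LabelVolume | None, box: BoundingBox
                 ) -> tuple[MultiModalVolume, LabelVolume | None]:
    """Crop all channels (and labels, identically) to ``box``."""
    for a, (lo, hi) in enumerate(zip(box.start, box.stop)):
        if lo < 0 or hi > vol.shape[a]:
            raise StructureError(f"bounding box {box} exceeds volume shape {vol.shape}")
    sl = (slice(None),) + box.slices
    cropped = MultiModalVolume(vol.data[sl].copy(), spacing=vol.spacing)
    clabels = LabelVolume(labels.data[box.slices].copy()) if labels is not None else None
    return cropped, clabels


def zscore_normalize(vol: MultiModalVolume, reduction_fraction: float = 1.0,
                     mode: str = "auto") -> tuple[MultiModalVolume, list[NormStats]]:
    """Per-channel z-score ``(X - mu) / sigma``.

    mode "all" uses every voxel; "nonzero" restricts mu/sigma to the channel's
    nonzero voxels and keeps originally-zero voxels at 0; "auto" selects
    "nonzero" when ``reduction_fraction`` (cropped / original voxel count) is
    below 3/4, i.e. when the crop shrank the image by more than one quarter.
    """
    if mode == "auto":
        mode = "nonzero" if reduction_fraction < 0.75 else "all"
    if mode not in ("all", "nonzero"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    out = np.empty_like(vol.data, dtype=np.float32)
    stats = []
    for ch in range(vol.data.shape[0]):
        x = vol.data[ch].astype(np.float32)
        if mode == "nonzero":
            mask = x != 0
            region = x[mask]
            if region.size == 0:
                raise DegenerateInputError(f"channel {ch}: no nonzero voxels to normalise")
        else:
            region = x.reshape(-1)
        mu = float(region.mean())
        sigma = float(region.std())
        if sigma == 0.0:
            raise DegenerateInputError(f"channel {ch}: zero standard deviation ({mode} region)")
        z = (x - mu) / sigma
        if mode == "nonzero":
            z[~mask] = 0.0
        out[ch] = z
        stats.append(NormStats(mu=mu, sigma=sigma, region=mode))
    return MultiModalVolume(out, spacing=vol.spacing), stats


def fit_to_patch(vol: MultiModalVolume, labels: LabelVolume | None,
                 patch_size: tuple[int, int, int]
                 ) -> tuple[MultiModalVolume, LabelVolume | None, FitInfo]:
    """Center-crop axes larger than the patch, symmetrically zero-pad smaller ones."""
    orig = vol.shape
    crop_start, pad_before, pad_after = [], [], []
    for o, p in zip(orig, patch_size):
        if o >= p:
            crop_start.append((o - p) // 2)
            pad_before.append(0)
            pad_after.append(0)
        else:
            crop_start.append(0)
            pad_before.append((p - o) // 2)
            pad_after.append(p - o - (p - o) // 2)
    sl = tuple(slice(c, c + min(o, p)) for c, o, p in zip(crop_start, orig, patch_size))
    pad4 = [(0, 0)] + [(b, a) for b, a in zip(pad_before, pad_after)]
    data = np.pad(vol.data[(slice(None),) + sl], pad4)
    fitted_labels = None
    if labels is not None:
        fitted_labels = LabelVolume(np.pad(labels.data[sl], pad4[1:]))
    info = FitInfo(original_shape=tuple(orig), crop_start=tuple(crop_start),
                   pad_before=tuple(pad_before))
    return MultiModalVolume(data, spacing=vol.spacing), fitted_labels, info


def unfit_from_patch(array: np.ndarray, info: FitInfo, fill=0) -> np.ndarray:
    """Place a patch-sized array back into the original extents (inverse of fit)."""
    patch = array.shape[-3:]
    inner_sl = tuple(
        slice(b, b + min(o, p))
        for b, o, p in zip(info.pad_before, info.original_shape, patch)
    )
    inner = array[(Ellipsis,) + inner_sl]
    out_shape = array.shape[:-3] + info.original_shape
    out = np.full(out_shape, fill, dtype=array.dtype)
    dest = tuple(
        slice(c, c + min(o, p))
        for c, o, p in zip(info.crop_start, info.original_shape, patch)
    )
    out[(Ellipsis,) + dest] = inner
    return out
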