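"""Segmentation evaluation: Dice, Hausdorff (and HD95), sensitivity.

Metrics are computed per nested region (ET, TC, WT) after encoding the
predicted and reference label volumes. Surface distances use boundary voxels
(face-connected erosion residue) and Euclidean distance, in voxel units by
default or millimetres when a spacing is supplied.

Conventions for degenerate cases (configurable per call): Dice of two empty
masks is 1.0; Hausdorff with an empty surface on either side is undefined
and reported as NaN (or a caller-chosen worst-case constant).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import LabelVolume, REGION_NAMES, encode_regions


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_masks(cls, pred: np.ndarray, gt: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        gt = np.asarray(gt, dtype=bool)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
        return cls(tp=int(np.sum(pred & gt)), fp=int(np.sum(pred & ~gt)),
                   fn=int(np.sum(~pred & gt)), tn=int(np.sum(~pred & ~gt)))


def dsc(counts: ConfusionCounts, both_empty: float = 1.0) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return both_empty
    return 2 * counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the reference region is empty."""
    if counts.tp + counts.fn == 0:
        return float("nan")
    return counts.tp / (counts.tp + counts.fn)


def surface_points(mask: np.ndarray,
                   spacing: tuple[float, float, float] | None = None) -> np.ndarray:
    """Coordinates of boundary voxels: mask minus its face-connected erosion."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    pts = np.argwhere(mask & ~interior).astype(np.float64)
    if spacing is not None:
        pts *= np.asarray(spacing)
    return pts


def _directed(d_from: np.ndarray, d_to: np.ndarray) -> np.ndarray:
    tree = cKDTree(d_to)
    dist, _ = tree.query(d_from, k=1)
    return np.atleast_1d(dist)


def hausdorff(s_points: np.ndarray, r_points: np.ndarray,
              percentile: float | None = None,
              empty_value: float = float("nan")) -> float:
    """Symmetric Hausdorff distance between two point sets.

    max over both directions of the sup (or given percentile) of
    nearest-neighbour distances. Either set empty -> ``empty_value``.
    """
    s_points = np.asarray(s_points, dtype=np.float64).reshape(-1, 3)
    r_points = np.asarray(r_points, dtype=np.float64).reshape(-1, 3)
    if len(s_points) == 0 or len(r_points) == 0:
        return empty_value
    d_sr = _directed(s_points, r_points)
    d_rs = _directed(r_points, s_points)
    if percentile is None:
        return float(max(d_sr.max(), d_rs.max()))
    return float(max(np.percentile(d_sr, percentile), np.percentile(d_rs, percentile)))


def hausdorff_masks(pred: np.ndarray, gt: np.ndarray,
                    spacing: tuple[float, float, float] | None = None,
                    percentile: float | None = None,
                    empty_value: float = float("nan")) -> float:
    return hausdorff(surface_points(gt, spacing), surface_points(pred, spacing),
                     percentile=percentile, empty_value=empty_value)


def evaluate_case(pred: LabelVolume, gt: LabelVolume,
                  spacing: tuple[float, float, float] | None = None,
                  hd_empty_value: float = float("nan"),
                  both_empty_dice: float = 1.0) -> list[dict]:
    """Per-region (ET, TC, WT) Dice, HD, HD95 and sensitivity records."""
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} != reference shape {gt.shape}")
    pred_regions = encode_regions(pred).data.astype(bool)
    gt_regions = encode_regions(gt).data.astype(bool)
    records = []
    for ch, region in enumerate(REGION_NAMES):
        counts = ConfusionCounts.from_masks(pred_regions[ch], gt_regions[ch])
        s = surface_points(gt_regions[ch], spacing)
        r = surface_points(pred_regions[ch], spacing)
        records.append({
            "region": region,
            "dice": dsc(counts, both_empty=both_empty_dice),
            "hd": hausdorff(s, r, empty_value=hd_empty_value),
            "hd95": hausdorff(s, r, percentile=95.0, empty_value=hd_empty_value),
            "sensitivity": sensitivity(counts),
        })
    return records
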