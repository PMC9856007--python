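"""BraTS-style case I/O and label-region conversion.

A case is a directory of co-registered NIfTI volumes, one per MRI modality
(T1, T1c, T2, FLAIR) and optionally a segmentation with the BraTS integer
convention: 1 = necrotic/non-enhancing tumor core, 2 = peritumoral edema,
4 = GD-enhancing tumor. Evaluation and the network operate on three nested
binary regions: ET = {4}, TC = {1,4}, WT = {1,2,4}, with ET ⊆ TC ⊆ WT.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
REGION_NAMES = ("ET", "TC", "WT")
VALID_LABELS = frozenset({0, 1, 2, 4})


class CaseLoadError(RuntimeError):
    """A modality or segmentation file is missing or unreadable."""


class StructureError(ValueError):
    """Shapes or values violate the BraTS case structure."""


@dataclasses.dataclass
class MultiModalVolume:
    """Four-channel intensity volume, channels ordered (T1, T1c, T2, FLAIR).

    data is (4, D, H, W); spacing is mm per spatial axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality_order: tuple[str, ...] = MODALITIES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise StructureError(f"expected (4, D, H, W) data, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise StructureError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclasses.dataclass
class LabelVolume:
    """Integer segmentation over the BraTS alphabet {0, 1, 2, 4}."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StructureError(f"labels must be 3-D, got shape {self.data.shape}")
        bad = np.setdiff1d(np.unique(self.data), sorted(VALID_LABELS))
        if bad.size:
            raise StructureError(f"illegal label values {bad.tolist()}; allowed {{0,1,2,4}}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class RegionMask:
    """Binary (3, D, H, W) array, channels (ET, TC, WT)."""

    data: np.ndarray
    channel_order: tuple[str, ...] = REGION_NAMES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise StructureError(f"expected (3, D, H, W) mask, got {self.data.shape}")
        if not np.isin(self.data, (0, 1)).all():
            raise StructureError("region mask must be binary")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def encode_regions(labels: LabelVolume) -> RegionMask:
    """Map BraTS labels to the nested (ET, TC, WT) channels.

    ET = label 4; TC = labels {1, 4}; WT = labels {1, 2, 4}. Nesting
    ET ⊆ TC ⊆ WT holds by construction.
    """
    lab = labels.data
    et = lab == 4
    tc = et | (lab == 1)
    wt = tc | (lab == 2)
    return RegionMask(np.stack([et, tc, wt]).astype(np.uint8))


def decode_regions(mask: RegionMask) -> LabelVolume:
    """Invert :func:`encode_regions` with innermost-wins priority.

    label 4 where ET, else 1 where TC, else 2 where WT, else 0. Voxels with
    inconsistent channels (e.g. ET on, TC off) resolve to the innermost active
    region, protecting enhancing-tumor voxels.
    """
    et, tc, wt = mask.data.astype(bool)
    out = np.zeros(et.shape, dtype=np.uint8)
    out[wt] = 2
    out[tc] = 1
    out[et] = 4
    return LabelVolume(out)


# -- NIfTI case directories ------------------------------------------------


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(path: Path | str, data: np.ndarray,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    nib.save(img, str(path))


def read_nifti(path: Path | str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def _find_file(case_dir: Path, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        hits = sorted(case_dir.glob(f"*_{suffix}{ext}"))
        if hits:
            return hits[0]
    return None


def read_case(case_dir: Path | str,
              suffixes: tuple[str, ...] = MODALITIES,
              seg_suffix: str = "seg") -> tuple[MultiModalVolume, LabelVolume | None]:
    """Load a BraTS-layout case directory.

    Expects one `*_<modality>.nii[.gz]` per modality and optionally a
    `*_seg.nii[.gz]`. BraTS volumes arrive co-registered at 1 mm isotropic, so
    no resampling is attempted; shapes are verified equal across files.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise CaseLoadError(f"case directory not found: {case_dir}")
    channels, spacing = [], None
    for suffix in suffixes:
        path = _find_file(case_dir, suffix)
        if path is None:
            raise CaseLoadError(f"missing modality '{suffix}' in {case_dir}")
        data, sp = read_nifti(path)
        channels.append(np.asarray(data, dtype=np.float32))
        spacing = spacing or sp
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise StructureError(f"modalities disagree on shape: {sorted(shapes)}")
    vol = MultiModalVolume(np.stack(channels), spacing=spacing)
    seg_path = _find_file(case_dir, seg_suffix)
    labels = None
    if seg_path is not None:
        seg, _ = read_nifti(seg_path)
        if seg.shape != vol.shape:
            raise StructureError(f"segmentation shape {seg.shape} != modality shape {vol.shape}")
        labels = LabelVolume(np.rint(np.asarray(seg)).astype(np.int16))
    return vol, labels


def write_case(case_dir: Path | str, vol: MultiModalVolume,
               labels: LabelVolume | None = None, case_id: str | None = None) -> Path:
    """Write a case in BraTS layout; returns the directory path."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    cid = case_id or case_dir.name
    for i, modality in enumerate(vol.modality_order):
        write_nifti(case_dir / f"{cid}_{modality}.nii.gz", vol.data[i], vol.spacing)
    if labels is not None:
        write_nifti(case_dir / f"{cid}_seg.nii.gz", labels.data, vol.spacing)
    return case_dir


def write_prediction(path: Path | str, labels: LabelVolume,
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Export a predicted segmentation as a single {0,1,2,4} NIfTI volume."""
    write_nifti(path, labels.data, spacing)
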