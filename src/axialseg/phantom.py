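"""Synthetic multi-modality brain-tumor phantoms with BraTS structure.

Each phantom is an ellipsoidal "head" of nonzero intensity on an exactly-zero
background (emulating skull-stripped MRI), containing one or more randomly
placed, rotated, anisotropic nested tumor ellipsoids: an edema shell
(label 2) around a core shell (label 1) around an enhancing centre (label 4).
The four modality channels share geometry but differ in tissue contrast —
enhancing tumor is brightest on the T1c-like channel and edema on the
FLAIR-like channel — with additive Gaussian noise inside the head.

These phantoms deliberately have none of the texture, bias fields or
inter-site variation of real MRI; they exist so the attention mechanism,
losses, metrics and training loop can be exercised end-to-end without data
downloads. Tumor/background imbalance mirrors the real task: under the
default configuration labelled voxels are well below 10% of the volume.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .io import LabelVolume, MultiModalVolume, write_case

#: mean intensity per tissue class, rows keyed by tissue, columns (T1, T1c, T2, FLAIR)
DEFAULT_CONTRAST = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (100.0, 100.0, 90.0, 90.0),
    "edema": (80.0, 85.0, 130.0, 150.0),
    "core": (70.0, 75.0, 110.0, 110.0),
    "enhancing": (90.0, 160.0, 100.0, 100.0),
}

_TISSUE_FOR_LABEL = {2: "edema", 1: "core", 4: "enhancing"}


class GenerationError(RuntimeError):
    """The requested tumor geometry cannot be placed inside the brain."""


@dataclasses.dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (160, 160, 112)
    background_margin: int = 8
    tumor_count_range: tuple[int, int] = (1, 2)
    #: (ET, TC, WT) radii as fractions of the tumor's outer radius
    subregion_radius_fractions: tuple[float, float, float] = (0.4, 0.7, 1.0)
    #: outer tumor radius range, as a fraction of the smallest brain semi-axis
    tumor_radius_fraction: tuple[float, float] = (0.15, 0.3)
    modality_contrast_table: dict = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 5.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        et, tc, wt = self.subregion_radius_fractions
        if not (0 < et < tc < wt):
            raise ValueError("subregion radius fractions must be strictly increasing ET < TC < WT")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _ellipsoid_mask(shape, center, semi_axes, rotation=None):
    """Boolean mask of a (rotated) ellipsoid, evaluated on a bounding box."""
    maxr = float(np.max(semi_axes))
    lo = np.maximum(np.floor(center - maxr - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + maxr + 2).astype(int), shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    coords = np.stack([g - c for g, c in zip(grids, center)], axis=-1).astype(np.float64)
    if rotation is not None:
        coords = coords @ rotation  # body frame
    rho = np.sqrt(((coords / np.asarray(semi_axes)) ** 2).sum(axis=-1))
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    return box, rho


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[MultiModalVolume, LabelVolume]:
    """Generate one synthetic case; deterministic given ``config.seed``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = np.asarray(config.shape)
    center = shape / 2.0
    brain_semi = (shape / 2.0 - config.background_margin) * rng.uniform(0.82, 0.92, size=3)
    if np.any(brain_semi <= 1):
        raise GenerationError(f"volume {config.shape} too small for margin "
                              f"{config.background_margin}")

    labels = np.zeros(tuple(shape), dtype=np.uint8)
    box, rho = _ellipsoid_mask(tuple(shape), center, brain_semi)
    brain = np.zeros(tuple(shape), dtype=bool)
    brain[box] = rho <= 1.0

    n_tumors = int(rng.integers(config.tumor_count_range[0], config.tumor_count_range[1] + 1))
    f_et, f_tc, f_wt = config.subregion_radius_fractions
    min_semi = float(brain_semi.min())
    for _ in range(n_tumors):
        placed = False
        for _attempt in range(200):
            r_outer = rng.uniform(*config.tumor_radius_fraction) * min_semi
            radii = r_outer * rng.uniform(0.7, 1.3, size=3)
            rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
            # keep the bounding sphere of the tumor inside the brain ellipsoid
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            slack = 1.0 - float(radii.max()) / min_semi
            if slack <= 0.05:
                continue
            t_center = center + (u * rng.uniform(0, slack * 0.9)) * brain_semi
            tbox, trho = _ellipsoid_mask(tuple(shape), t_center, radii * f_wt, rotation=rot)
            region = labels[tbox]
            region[trho <= 1.0] = 2
            region[trho <= f_tc / f_wt] = 1
            region[trho <= f_et / f_wt] = 4
            labels[tbox] = region
            placed = True
            break
        if not placed:
            raise GenerationError("could not place tumor inside the brain; "
                                  "reduce tumor_radius_fraction or the margin")
    labels[~brain] = 0

    table = config.modality_contrast_table
    data = np.zeros((4,) + tuple(shape), dtype=np.float32)
    for ch in range(4):
        vol = np.full(tuple(shape), table["background"][ch], dtype=np.float32)
        vol[brain] = table["brain"][ch]
        for lab, tissue in _TISSUE_FOR_LABEL.items():
            vol[labels == lab] = table[tissue][ch]
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=vol.shape).astype(np.float32)
            vol[brain] += noise[brain]  # background stays exactly zero
        data[ch] = vol
    return (MultiModalVolume(data, spacing=config.spacing),
            LabelVolume(labels))


def small_phantom_config(seed: int = 0) -> PhantomConfig:
    """Desk-scale phantom: 48-cube grid whose cropped head fits a 32-cube
    patch, with tumors enlarged relative to the head so that subregion
    statistics stay meaningful at this resolution."""
    return PhantomConfig(shape=(48, 48, 48), background_margin=4,
                         tumor_count_range=(1, 1),
                         tumor_radius_fraction=(0.25, 0.45), seed=seed)


def case_seeds(cohort_seed: int, n: int) -> list[int]:
    """Deterministic per-case seeds derived from one cohort seed."""
    ss = np.random.SeedSequence(cohort_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def generate_cases(n: int, config: PhantomConfig, seed: int | None = None
                   ) -> list[tuple[MultiModalVolume, LabelVolume]]:
    """Generate ``n`` independent in-memory cases from one cohort seed."""
    seed = config.seed if seed is None else seed
    out = []
    for s in case_seeds(seed, n):
        cfg = dataclasses.replace(config, seed=s)
        out.append(generate_phantom(cfg))
    return out


def generate_cohort(n: int, config: PhantomConfig, out_dir: Path | str,
                    seed: int | None = None) -> list[Path]:
    """Write ``n`` cases in BraTS layout under ``out_dir``; returns case dirs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirs = []
    seed = config.seed if seed is None else seed
    for i, s in enumerate(case_seeds(seed, n)):
        cfg = dataclasses.replace(config, seed=s)
        vol, labels = generate_phantom(cfg)
        case_dir = out_dir / f"phantom_{i:03d}"
        write_case(case_dir, vol, labels)
        dirs.append(case_dir)
    return dirs
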