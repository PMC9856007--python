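"""Training and inference engine.

Training follows the recipe the architecture was designed for: Adam at an
initial learning rate of 1e-4 decayed polynomially, lr(e) = lr0 * (1 -
e/max_epoch)^0.9; batch size 2; 250 mini-batches per epoch, each batch built
by sampling training cases with replacement and drawing one augmented patch
per case; five-fold cross-validation over the cohort; the deep-supervised
hybrid Dice+BCE loss. All randomness (splits, weight init, sampling,
augmentation) derives from one root seed through named substreams.

Whole-volume inference tiles the preprocessed volume with patch-sized
windows at 50% overlap, blends the sigmoid outputs under a Gaussian window
weight, thresholds each region channel at 0.5, decodes the nested regions to
BraTS labels, and maps the result back into the original voxel grid.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import grad
from .augment import AugmentConfig, augment_case
from .io import (LabelVolume, MultiModalVolume, RegionMask, decode_regions,
                 encode_regions, read_case, read_nifti)
from .losses import LossConfig, hybrid_total_loss
from .metrics import ConfusionCounts, dsc, evaluate_case
from .network import AABTSNet, NetworkConfig, build_model
from .optim import Adam
from .preprocess import (crop_to_bbox, fit_to_patch, nonzero_bbox,
                         unfit_from_patch, zscore_normalize)


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 2
    max_epoch: int = 300
    iters_per_epoch: int = 250
    lr0: float = 1e-4
    poly_power: float = 0.9
    folds: int = 5
    seed: int = 0
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("batch_size must be >= 1 and lr0 positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def tiny_train_config(seed: int = 0, max_epoch: int = 12, iters_per_epoch: int = 25,
                      lr0: float = 1e-3) -> TrainConfig:
    """CPU-scale configuration: 32-cube patches, 4 levels, 8 base filters.

    The architecture, loss and schedule are unchanged; only capacity, patch
    size and optimisation length are scaled to desk hardware. The higher
    learning rate compensates for the tiny number of optimisation steps.
    """
    net = NetworkConfig(base_filters=8, max_filters=64, levels=4,
                        patch_size=(32, 32, 32))
    return TrainConfig(max_epoch=max_epoch, iters_per_epoch=iters_per_epoch,
                       lr0=lr0, seed=seed, network=net)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Polynomial decay lr0 * (1 - epoch/max_epoch)^power."""
    if not 0 <= epoch < config.max_epoch:
        raise ValueError(f"epoch {epoch} outside 0..{config.max_epoch - 1}")
    return config.lr0 * (1.0 - epoch / config.max_epoch) ** config.poly_power


def kfold_split(case_ids: Sequence, k: int = 5, seed: int = 0) -> list[tuple[list, list]]:
    """Random disjoint k-fold partitions (sizes differing by at most one).

    Returns k (train_ids, val_ids) pairs; the union of validation folds is
    the whole cohort.
    """
    ids = list(case_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} cases for {k}-fold cross-validation")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(f) for f in np.array_split(perm, k)]
    return [(sum((f for j, f in enumerate(folds) if j != i), []), folds[i])
            for i in range(k)]


# -- case preparation ------------------------------------------------------


@dataclasses.dataclass
class PreparedCase:
    """A case after crop / z-score / patch fitting, ready for the network."""

    image: np.ndarray     # (4, *patch) float32
    regions: np.ndarray   # (3, *patch) uint8


def prepare_case(vol: MultiModalVolume, labels: LabelVolume | None,
                 patch_size: tuple[int, int, int]) -> tuple[PreparedCase | np.ndarray, dict]:
    """Crop to nonzero, z-score (nonzero statistics when the crop removed more
    than a quarter of the voxels), and fit to the patch size. Returns the
    prepared arrays plus the geometry needed to invert the mapping."""
    box = nonzero_bbox(vol)
    cropped, clabels = crop_to_bbox(vol, labels, box)
    reduction = np.prod(cropped.shape) / np.prod(vol.shape)
    normed, stats = zscore_normalize(cropped, reduction_fraction=float(reduction))
    fitted, flabels, info = fit_to_patch(normed, clabels, patch_size)
    geometry = {"bbox": box, "fit": info, "original_shape": vol.shape,
                "norm_stats": stats}
    if flabels is not None:
        prepared = PreparedCase(image=fitted.data.astype(np.float32),
                                regions=encode_regions(flabels).data)
        return prepared, geometry
    return fitted.data.astype(np.float32), geometry


# -- training --------------------------------------------------------------


@dataclasses.dataclass
class TrainResult:
    model: AABTSNet
    log: list[dict]
    best_state: dict
    best_mean_dice: float


def _validation_dice(model: AABTSNet, prepared: Sequence[PreparedCase]) -> dict[str, float]:
    per_region = {"ET": [], "TC": [], "WT": []}
    for case in prepared:
        with grad.no_grad():
            main, _ = model(grad.Tensor(case.image[None]))
        pred = (main.data[0] >= 0.5).astype(np.uint8)
        for ch, region in enumerate(("ET", "TC", "WT")):
            counts = ConfusionCounts.from_masks(pred[ch], case.regions[ch])
            per_region[region].append(dsc(counts))
    return {k: float(np.mean(v)) for k, v in per_region.items()}


def train_fold(cases: Sequence[tuple[MultiModalVolume, LabelVolume]],
               config: TrainConfig, fold: int | None = None,
               val_cases: Sequence[tuple[MultiModalVolume, LabelVolume]] | None = None,
               verbose: bool = False) -> TrainResult:
    """Train on a cohort (or one cross-validation fold of it).

    With ``fold`` given, the cohort is split by :func:`kfold_split` and the
    indexed fold held out; otherwise ``val_cases`` (possibly empty) is the
    explicit validation set. Returns the model bearing its final weights,
    the per-epoch log, and the best-validation-Dice weight snapshot.
    """
    if fold is not None:
        splits = kfold_split(range(len(cases)), config.folds, config.seed)
        train_ids, val_ids = splits[fold]
        train_cases = [cases[i] for i in train_ids]
        val_cases = [cases[i] for i in val_ids]
    else:
        train_cases = list(cases)
        val_cases = list(val_cases or [])
    if not train_cases:
        raise ValueError("no training cases")

    patch = tuple(config.network.patch_size)
    prepared = [prepare_case(v, l, patch)[0] for v, l in train_cases]
    prepared_val = [prepare_case(v, l, patch)[0] for v, l in val_cases]

    root = np.random.SeedSequence(config.seed)
    init_seed, sample_seed, augment_seed = (int(s) for s in root.generate_state(3) % (2 ** 31))
    model = build_model(config.network, seed=init_seed)
    opt = Adam(model.parameters(), lr=config.lr0)
    sample_rng = np.random.default_rng(sample_seed)
    augment_rng = np.random.default_rng(augment_seed)

    log: list[dict] = []
    best_state = model.state_dict()
    best_mean = -1.0
    for epoch in range(config.max_epoch):
        opt.lr = lr_schedule(epoch, config)
        losses = []
        for _ in range(config.iters_per_epoch):
            idx = sample_rng.integers(0, len(prepared), size=config.batch_size)
            images, targets = [], []
            for i in idx:
                case = prepared[i]
                if config.augment.p_apply > 0:
                    vol_a, reg_a = augment_case(
                        MultiModalVolume(case.image), RegionMask(case.regions),
                        augment_rng, config.augment)
                    images.append(vol_a.data)
                    targets.append(reg_a.data)
                else:
                    images.append(case.image)
                    targets.append(case.regions)
            x = grad.Tensor(np.stack(images))
            y = np.stack(targets).astype(np.float32)
            main, aux = model(x)
            loss = hybrid_total_loss(main, aux, y, config.loss)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if prepared_val:
            val = _validation_dice(model, prepared_val)
            entry.update({f"val_dice_{k.lower()}": v for k, v in val.items()})
            mean_dice = float(np.mean(list(val.values())))
            entry["val_dice_mean"] = mean_dice
            if mean_dice > best_mean:
                best_mean = mean_dice
                best_state = model.state_dict()
        else:
            best_state = model.state_dict()
        log.append(entry)
        if verbose:
            print(json.dumps(entry))
    return TrainResult(model=model, log=log, best_state=best_state,
                       best_mean_dice=best_mean)


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path: Path | str, model: AABTSNet) -> None:
    """Serialise weights and the embedded network configuration (npz)."""
    cfg = dataclasses.asdict(model.config)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: Path | str) -> AABTSNet:
    with np.load(str(path)) as archive:
        cfg_dict = json.loads(bytes(archive["__config__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    for key in ("patch_size", "aam_levels", "ds_head_levels", "attention_base",
                "aam_axis_order"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(NetworkConfig(**cfg_dict))
    model.load_state_dict(state)
    return model


# -- inference -------------------------------------------------------------


def _window_starts(extent: int, patch: int) -> list[int]:
    if extent <= patch:
        return [0]
    step = max(patch // 2, 1)
    starts = list(range(0, extent - patch, step))
    starts.append(extent - patch)
    return sorted(set(starts))


def _gaussian_window(patch: tuple[int, int, int]) -> np.ndarray:
    axes = [np.exp(-0.5 * ((np.arange(p) - (p - 1) / 2) / (p / 8)) ** 2) for p in patch]
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return (w / w.max()).astype(np.float32)


def predict_case(model: AABTSNet, vol: MultiModalVolume,
                 blend: str = "gaussian") -> LabelVolume:
    """Segment a whole volume; output matches the input geometry.

    ``blend="gaussian"`` tiles with 50%-overlap windows and Gaussian-weighted
    averaging of the sigmoid maps; ``blend="center"`` uses a single
    center-cropped window (strict patch mode).
    """
    patch = tuple(model.config.patch_size)
    box = nonzero_bbox(vol)
    cropped, _ = crop_to_bbox(vol, None, box)
    reduction = np.prod(cropped.shape) / np.prod(vol.shape)
    normed, _ = zscore_normalize(cropped, reduction_fraction=float(reduction))

    if blend == "center":
        fitted, _, info = fit_to_patch(normed, None, patch)
        with grad.no_grad():
            main, _ = model(grad.Tensor(fitted.data[None]))
        probs = main.data[0]
        probs_crop = unfit_from_patch(probs, info, fill=0.0)
    else:
        # pad up to at least the patch on every axis, then tile
        pad_target = tuple(max(s, p) for s, p in zip(normed.shape, patch))
        fitted, _, info = fit_to_patch(normed, None, pad_target)
        data = fitted.data
        weight = _gaussian_window(patch)
        acc = np.zeros((3,) + pad_target, dtype=np.float32)
        wsum = np.zeros(pad_target, dtype=np.float32)
        for d0 in _window_starts(pad_target[0], patch[0]):
            for h0 in _window_starts(pad_target[1], patch[1]):
                for w0 in _window_starts(pad_target[2], patch[2]):
                    sl = (slice(d0, d0 + patch[0]), slice(h0, h0 + patch[1]),
                          slice(w0, w0 + patch[2]))
                    tile = data[(slice(None),) + sl]
                    with grad.no_grad():
                        main, _ = model(grad.Tensor(tile[None]))
                    acc[(slice(None),) + sl] += main.data[0] * weight
                    wsum[sl] += weight
        probs = acc / np.maximum(wsum, 1e-8)
        probs_crop = unfit_from_patch(probs, info, fill=0.0)

    mask = RegionMask((probs_crop >= 0.5).astype(np.uint8))
    labels_crop = decode_regions(mask)
    full = np.zeros(vol.shape, dtype=np.uint8)
    full[box.slices] = labels_crop.data
    return LabelVolume(full)


# -- cohort evaluation -----------------------------------------------------


def evaluate_pairs(pairs: Sequence[tuple[str, LabelVolume, LabelVolume]],
                   spacing: tuple[float, float, float] | None = None) -> pd.DataFrame:
    """Per-case, per-region metric table plus cohort-mean rows."""
    rows = []
    for case_id, pred, gt in pairs:
        for rec in evaluate_case(pred, gt, spacing=spacing):
            rows.append({"case": case_id, **rec})
    df = pd.DataFrame(rows)
    means = (df.groupby("region", sort=False)
             .mean(numeric_only=True).reset_index())
    means.insert(0, "case", "MEAN")
    return pd.concat([df, means], ignore_index=True)


def evaluate_cohort(pred_dir: Path | str, gt_dir: Path | str,
                    csv_path: Path | str | None = None) -> pd.DataFrame:
    """Evaluate `<case>.nii[.gz]` predictions against BraTS-layout reference
    case directories with matching names. Unmatched ids are skipped with a
    warning; an empty intersection is an error."""
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    preds = {p.name.replace(".nii.gz", "").replace(".nii", ""): p
             for p in sorted(pred_dir.glob("*.nii*"))}
    gts = {d.name: d for d in sorted(gt_dir.iterdir()) if d.is_dir()}
    common = sorted(set(preds) & set(gts))
    for missing in sorted(set(preds) ^ set(gts)):
        warnings.warn(f"case {missing!r} present on only one side; skipped")
    if not common:
        raise ValueError(f"no matching case ids between {pred_dir} and {gt_dir}")
    pairs = []
    for cid in common:
        data, _ = read_nifti(preds[cid])
        pred = LabelVolume(np.rint(np.asarray(data)).astype(np.int16))
        _, gt = read_case(gts[cid])
        if gt is None:
            warnings.warn(f"case {cid!r} has no reference segmentation; skipped")
            continue
        pairs.append((cid, pred, gt))
    df = evaluate_pairs(pairs)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df
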