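"""Schedule, cross-validation splits, training behaviour, inference and
checkpointing."""

import dataclasses

import numpy as np
import pytest

import axialseg as ax
from axialseg.engine import (PreparedCase, kfold_split, load_checkpoint,
                             lr_schedule, predict_case, prepare_case,
                             save_checkpoint, tiny_train_config, train_fold)


class TestSchedule:
    def test_initial_learning_rate(self):
        assert lr_schedule(0, ax.TrainConfig()) == pytest.approx(1e-4)

    def test_midpoint_value_matches_formula(self):
        """Half-way through training the polynomial decay gives
        1e-4 * 0.5^0.9, evaluated independently."""
        assert lr_schedule(150, ax.TrainConfig()) == pytest.approx(
            1e-4 * 0.5 ** 0.9, rel=1e-12)

    def test_monotone_decreasing(self):
        cfg = ax.TrainConfig()
        vals = [lr_schedule(e, cfg) for e in range(0, 300, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(300, ax.TrainConfig())


class TestKFold:
    def test_partition_properties(self):
        ids = [f"c{i}" for i in range(10)]
        splits = kfold_split(ids, k=5, seed=3)
        assert len(splits) == 5
        val_union = []
        for train, val in splits:
            assert len(val) == 2 and len(train) == 8
            assert set(train) | set(val) == set(ids)
            assert not set(train) & set(val)
            val_union += val
        assert sorted(val_union) == sorted(ids)

    def test_uneven_sizes_differ_by_at_most_one(self):
        splits = kfold_split(range(13), k=5, seed=0)
        sizes = [len(val) for _, val in splits]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_given_seed(self):
        a = kfold_split(range(20), k=5, seed=9)
        b = kfold_split(range(20), k=5, seed=9)
        assert a == b

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            kfold_split([1, 2], k=5)


def test_prepare_case_outputs_patch_sized(phantom_pair):
    vol, labels = phantom_pair
    prep, geom = prepare_case(vol, labels, (32, 32, 32))
    assert prep.image.shape == (4, 32, 32, 32)
    assert prep.regions.shape == (3, 32, 32, 32)
    assert geom["original_shape"] == vol.shape


def test_training_loss_descends(small_cohort):
    """Two epochs on a handful of phantoms already reduce the training loss."""
    cfg = tiny_train_config(seed=1, max_epoch=2, iters_per_epoch=8)
    cfg = dataclasses.replace(cfg, augment=ax.AugmentConfig(p_apply=0.0))
    res = train_fold(small_cohort[:4], cfg)
    assert res.log[-1]["train_loss"] < res.log[0]["train_loss"]


def test_deterministic_training_runs(small_cohort):
    """Fixed seeds and no augmentation: two runs give identical loss curves."""
    cfg = tiny_train_config(seed=5, max_epoch=1, iters_per_epoch=4)
    cfg = dataclasses.replace(cfg, augment=ax.AugmentConfig(p_apply=0.0))
    r1 = train_fold(small_cohort[:3], cfg)
    r2 = train_fold(small_cohort[:3], cfg)
    assert r1.log == r2.log


def test_generalizes_to_held_out_phantoms(trained_tiny, small_cohort, tiny_config):
    """Tiny configuration trained on 16 phantoms segments whole tumor on the
    4 unseen phantoms with mean DSC at or above 0.7, through the full
    sliding-window prediction path."""
    model = trained_tiny.model
    wt_scores = []
    for vol, labels in small_cohort[16:]:
        pred = predict_case(model, vol)
        rec = {r["region"]: r for r in ax.evaluate_case(pred, labels)}
        wt_scores.append(rec["WT"]["dice"])
    assert np.mean(wt_scores) >= 0.7


def test_prediction_matches_original_geometry(trained_tiny, small_cohort):
    vol, _ = small_cohort[16]
    pred = predict_case(trained_tiny.model, vol)
    assert pred.shape == vol.shape
    assert set(np.unique(pred.data)) <= {0, 1, 2, 4}
    # voxels outside the nonzero bounding box are background by construction
    box = ax.nonzero_bbox(vol)
    mask = np.ones(vol.shape, dtype=bool)
    mask[box.slices] = False
    assert (pred.data[mask] == 0).all()


def test_center_blend_single_window(trained_tiny, small_cohort):
    vol, _ = small_cohort[17]
    pred = predict_case(trained_tiny.model, vol, blend="center")
    assert pred.shape == vol.shape


def test_checkpoint_round_trip_bit_identical(tmp_path, trained_tiny, small_cohort):
    """Save -> load -> predict reproduces the pre-save prediction exactly."""
    model = trained_tiny.model
    vol, _ = small_cohort[18]
    before = predict_case(model, vol)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model)
    reloaded = load_checkpoint(path)
    after = predict_case(reloaded, vol)
    np.testing.assert_array_equal(before.data, after.data)


def test_evaluate_cohort_end_to_end(tmp_path, small_cohort, trained_tiny):
    gt_dir = tmp_path / "gt"
    pred_dir = tmp_path / "pred"
    pred_dir.mkdir()
    for i, (vol, labels) in enumerate(small_cohort[16:18]):
        cid = f"case_{i}"
        ax.write_case(gt_dir / cid, vol, labels)
        pred = predict_case(trained_tiny.model, vol)
        ax.write_prediction(pred_dir / f"{cid}.nii.gz", pred)
    df = ax.evaluate_cohort(pred_dir, gt_dir, csv_path=tmp_path / "report.csv")
    assert (tmp_path / "report.csv").exists()
    mean_rows = df[df["case"] == "MEAN"]
    assert set(mean_rows["region"]) == {"ET", "TC", "WT"}
    # cohort mean equals the hand-averaged per-case values
    per_case = df[(df["case"] != "MEAN") & (df["region"] == "WT")]["dice"]
    got = mean_rows[mean_rows["region"] == "WT"]["dice"].iloc[0]
    assert got == pytest.approx(per_case.mean())


def test_evaluate_cohort_identity_predictions(tmp_path, small_cohort):
    gt_dir = tmp_path / "gt"
    pred_dir = tmp_path / "pred"
    pred_dir.mkdir()
    for i, (vol, labels) in enumerate(small_cohort[:2]):
        cid = f"case_{i}"
        ax.write_case(gt_dir / cid, vol, labels)
        ax.write_prediction(pred_dir / f"{cid}.nii.gz", labels)
    df = ax.evaluate_cohort(pred_dir, gt_dir)
    assert (df[df["case"] == "MEAN"]["dice"] == 1.0).all()


def test_evaluate_cohort_no_overlap_errors(tmp_path, small_cohort):
    gt_dir = tmp_path / "gt"
    pred_dir = tmp_path / "pred"
    pred_dir.mkdir()
    vol, labels = small_cohort[0]
    ax.write_case(gt_dir / "a", vol, labels)
    ax.write_prediction(pred_dir / "b.nii.gz", labels)
    with pytest.raises(ValueError, match="matching"), pytest.warns(UserWarning):
        ax.evaluate_cohort(pred_dir, gt_dir)
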