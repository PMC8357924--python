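import math

import numpy as np
import pytest

from negvol import (
    ConfigError,
    DivergenceError,
    MetricError,
    NetworkConfig,
    TrainConfig,
    augment,
    build_model,
    ce_loss,
    combined_loss,
    cross_validate,
    dice_loss,
    evaluate,
    flip_lr,
    train_model,
)
from negvol.training import hausdorff_masks

TINY_NET = NetworkConfig(architecture="vnet", base_channels=4, depth=2,
                         kernel_size=3, patch_shape=(16, 16, 16), num_classes=2)


def _two_ball_patches():
    rng = np.random.default_rng(0)
    out = []
    for s in range(2):
        lab = np.zeros((16, 16, 16), dtype=np.uint8)
        idx = np.indices((16, 16, 16))
        lab[((idx[0] - 8 - s) ** 2 + (idx[1] - 8) ** 2 + (idx[2] - 8) ** 2) < 25] = 1
        img = lab * 1.0 + rng.normal(0, 0.1, lab.shape)
        out.append((img.astype(np.float32), lab))
    return out


# -------------------------------------------------------------------- losses

def test_dice_loss_closed_forms():
    p = np.zeros((4, 4, 4)); t = np.zeros((4, 4, 4))
    p.flat[:2] = 1; t.flat[1:3] = 1
    assert dice_loss(p, t) == pytest.approx(0.5, abs=1e-4)  # |P|=2,|T|=2,overlap 1
    assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-4)
    disjoint = np.zeros((4, 4, 4)); disjoint.flat[10:12] = 1
    assert dice_loss(disjoint, t) == pytest.approx(1.0, abs=1e-3)


def test_ce_loss_closed_forms():
    target = np.zeros((3, 3, 3), dtype=np.uint8)
    uniform = np.full((2, 3, 3, 3), 0.5)
    assert ce_loss(uniform, target) == pytest.approx(math.log(2))
    perfect = np.zeros((2, 3, 3, 3)); perfect[0] = 1.0
    assert ce_loss(perfect, target) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        ce_loss(np.full((2, 3, 3, 3), 0.9), target)  # not normalized


def test_combined_loss_linearity():
    p = np.zeros((4, 4, 4)); t = np.zeros((4, 4, 4))
    p.flat[:2] = 1; t.flat[1:3] = 1
    total = combined_loss(p, t, (1.0, 1.0))
    assert total == pytest.approx(dice_loss(p, t) + ce_loss(np.clip(p, 0, 1), t))


def test_dice_loss_and_dice_score_are_complementary():
    """dice_loss + DICE/100 = 1 for hard predictions."""
    rng = np.random.default_rng(5)
    pred = (rng.random((10, 10, 10)) > 0.6).astype(float)
    truth = (rng.random((10, 10, 10)) > 0.6).astype(float)
    d_pct, _, _ = evaluate(pred, truth)
    assert dice_loss(pred, truth) + d_pct / 100 == pytest.approx(1.0, abs=1e-4)


# ------------------------------------------------------------------ evaluate

def test_evaluate_identical_and_shifted():
    a = np.zeros((20, 20, 20)); a[5:9, 5:9, 5:9] = 1
    d, c, h = evaluate(a, a)
    assert d == pytest.approx(100.0) and h == 0.0
    d, c, h = evaluate(np.roll(a, 3, axis=0), a, spacing=(1, 1, 1))
    assert h == pytest.approx(3.0)


def test_evaluate_closed_form_dice():
    pred = np.zeros((10, 10, 10)); truth = np.zeros((10, 10, 10))
    pred.flat[:100] = 1; truth.flat[20:120] = 1  # |P|=|T|=100, overlap 80
    d, _, _ = evaluate(pred, truth)
    assert d == pytest.approx(80.0)


def test_evaluate_both_empty_is_undefined():
    z = np.zeros((4, 4, 4))
    with pytest.raises(MetricError):
        evaluate(z, z)


def test_hausdorff_masks_equals_brute_force_on_small_masks():
    rng = np.random.default_rng(7)
    spacing = np.array([0.7, 1.0, 1.3])
    for _ in range(5):
        a = rng.random((12, 12, 12)) > 0.8
        b = rng.random((12, 12, 12)) > 0.8
        if not (a.any() and b.any()):
            continue
        from scipy import ndimage
        surf = lambda m: m & ~ndimage.binary_erosion(m)
        pa = np.argwhere(surf(a)) * spacing
        pb = np.argwhere(surf(b)) * spacing
        d2 = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        brute = max(d2.min(axis=1).max(), d2.min(axis=0).max())
        assert hausdorff_masks(a, b, spacing) == pytest.approx(brute)


# ---------------------------------------------------------------- augmentation

def test_augment_deterministic_and_involution():
    img, msk = _two_ball_patches()[0]
    a1 = augment(img, msk, seed=5)
    a2 = augment(img, msk, seed=5)
    assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])
    assert np.array_equal(flip_lr(flip_lr(img)), img)


def test_augment_flip_and_translation_conserve_mask_volume():
    img, msk = _two_ball_patches()[0]
    # flips and integer translations move voxels without creating/destroying
    # them (away from borders)
    _, out = augment(img, msk, seed=3, transforms=("flip",), probability=1.0)
    assert out.sum() == msk.sum()


def test_augment_mask_stays_binary():
    img, msk = _two_ball_patches()[0]
    _, out = augment(img, msk, seed=9, probability=1.0)
    assert set(np.unique(out)) <= {0, 1}


# ------------------------------------------------------------------ training

def test_overfit_smoke_two_patches():
    model = build_model(TINY_NET, seed=0)
    cfg = TrainConfig(learning_rate=1e-3, epochs=10, weight_decay=0.0, seed=0)
    model, hist = train_model(model, _two_ball_patches(), cfg)
    assert hist[-1] < hist[0]


def test_training_is_deterministic_and_epochs_zero_is_identity():
    data = _two_ball_patches()
    cfg = TrainConfig(learning_rate=1e-3, epochs=3, weight_decay=0.0, seed=0)
    _, h1 = train_model(build_model(TINY_NET, seed=0), data, cfg)
    _, h2 = train_model(build_model(TINY_NET, seed=0), data, cfg)
    assert h1 == h2
    fresh = build_model(TINY_NET, seed=0)
    trained, hist = train_model(build_model(TINY_NET, seed=0), data, TrainConfig(epochs=0))
    assert hist == []
    assert all(np.array_equal(p.data, q.data) for p, q in zip(fresh.parameters, trained.parameters))


def test_divergence_reports_epoch():
    data = _two_ball_patches()
    # absurd learning rate forces a non-finite loss within a few epochs
    cfg = TrainConfig(learning_rate=1e6, epochs=50, weight_decay=0.0, seed=0)
    with pytest.raises(DivergenceError):
        train_model(build_model(TINY_NET, seed=0), data, cfg)


# ----------------------------------------------------------- cross-validation

def test_cross_validate_partitions_patients(small_cohort):
    from negvol.studies import SEG_NET, cohort_to_patients

    patients = cohort_to_patients(small_cohort)
    cfg = TrainConfig(learning_rate=1e-3, epochs=1, weight_decay=0.0, folds=2, seed=0)
    table = cross_validate(patients, cfg, SEG_NET)
    seen = [pid for fold in sorted(table["fold"].unique())
            for pid in table[table.fold == fold]["val_patients"].iloc[0]]
    assert sorted(seen) == [p["patient_id"] for p in patients]  # exact partition
    assert set(table["score"]) == {"DICE", "CE", "HD"}


def test_metrics_table_layout():
    import pandas as pd
    from negvol.training import metrics_table

    fold_table = pd.DataFrame([
        {"fold": 0, "score": s, "mean": m, "sd": 0.1}
        for s, m in (("DICE", 95.0), ("CE", 0.2), ("HD", 1.5))
    ] + [
        {"fold": 1, "score": s, "mean": m, "sd": 0.1}
        for s, m in (("DICE", 93.0), ("CE", 0.3), ("HD", 2.5))
    ])
    table = metrics_table({"MC": {"vnet": fold_table}})
    assert list(table.columns) == ["object", "score", "architecture", "mean", "sd"]
    row = table[(table.object == "MC") & (table.score == "DICE")].iloc[0]
    assert row["mean"] == 94.0 and row["architecture"] == "vnet"


def test_cross_validate_requires_enough_patients(small_cohort):
    from negvol.studies import SEG_NET, cohort_to_patients

    patients = cohort_to_patients(small_cohort[:2])
    with pytest.raises(ConfigError):
        cross_validate(patients, TrainConfig(folds=5), SEG_NET)
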