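"""Losses, evaluation metrics, augmentation, patch training and
patient-wise cross-validation.

The loss is the linear combination of cross-entropy and soft Dice used to
optimize both per-voxel and overlap quality; Dice score (percent),
cross-entropy and the symmetric Hausdorff distance (mm, on surface voxels)
are the evaluation metrics.  Cross-validation folds partition *patients*,
never patches -- both joints of one patient always share a fold, so no
validation anatomy leaks into training.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.model_selection import KFold

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .errors import ConfigError, DivergenceError, MetricError
from .io_formats import Mask, Volume
from .nets import NetworkConfig, SegmentationModel, build_model

_EPS = 1e-5  # soft-Dice smoothing


@dataclass
class TrainConfig:
    """Optimization settings (Adam throughout).

    Defaults follow the segmentation stage: initial learning rate 1e-4,
    beta1 = 0.9, beta2 = 0.99, weight decay 0.01, combined Dice + CE loss
    with unit weights.  The localization stage uses learning rate 1e-3.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 0.01
    epochs: int = 100
    batch_size: int = 1
    loss: str = "dice+ce"
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (dice, ce)
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ConfigError("beta1/beta2 must be in (0, 1)")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.loss not in ("ce", "dice", "dice+ce"):
            raise ConfigError(f"unknown loss {self.loss!r}")
        w = tuple(float(x) for x in self.loss_weights)
        if any(x < 0 for x in w) or not any(w):
            raise ConfigError("loss_weights must be >= 0 and not both zero")
        self.loss_weights = w


# ---------------------------------------------------------------------------
# losses (public numpy forms + autodiff forms used during training)
# ---------------------------------------------------------------------------

def _foreground_prob(pred: np.ndarray) -> np.ndarray:
    """Foreground probability from (C, ...) class probabilities, or the
    array itself if already a single foreground map."""
    pred = np.asarray(pred, dtype=float)
    if pred.ndim == 4:
        return pred[1:].sum(axis=0)
    return pred


def dice_loss(pred: np.ndarray, target: np.ndarray | Mask) -> float:
    """Soft Dice loss ``1 - (2|P.T| + eps) / (|P| + |T| + eps)`` over the
    foreground probability; 0 for a perfect hard prediction, ~1 for a
    disjoint one."""
    t = np.asarray(target.data if isinstance(target, Mask) else target, dtype=float)
    p = _foreground_prob(pred)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    inter = float((p * t).sum())
    return 1.0 - (2 * inter + _EPS) / (float(p.sum()) + float(t.sum()) + _EPS)


def ce_loss(pred: np.ndarray, target: np.ndarray | Mask) -> float:
    """Mean voxelwise negative log-probability of the true class.

    ``pred`` is either (C, ...) class probabilities (must sum to 1 over
    channels) or a single foreground-probability map of a binary problem.
    """
    t = np.asarray(target.data if isinstance(target, Mask) else target)
    pred = np.asarray(pred, dtype=float)
    if pred.ndim == 4:
        sums = pred.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError("class probabilities must sum to 1 over channels")
        if t.shape != pred.shape[1:]:
            raise ValueError("shape mismatch between prediction and target")
        idx = t.astype(np.int64)
        p_true = np.take_along_axis(pred, idx[None], axis=0)[0]
    else:
        if t.shape != pred.shape:
            raise ValueError("shape mismatch between prediction and target")
        if pred.min() < 0 or pred.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        p_true = np.where(t > 0, pred, 1.0 - pred)
    return float(-np.log(np.clip(p_true, 1e-12, None)).mean())


def combined_loss(pred, target, weights=(1.0, 1.0)) -> float:
    """weights[0] * dice_loss + weights[1] * ce_loss."""
    return weights[0] * dice_loss(pred, target) + weights[1] * ce_loss(pred, target)


def _loss_tensor(logits: Tensor, target: np.ndarray, cfg: TrainConfig) -> Tensor:
    """Differentiable loss on logits (C, D, H, W); target is an integer
    label volume."""
    num_classes = logits.shape[0]
    probs = ad.softmax_channels(logits)
    onehot = np.eye(num_classes, dtype=np.float32)[target.astype(np.int64)]
    onehot = np.moveaxis(onehot, -1, 0)
    t = Tensor(onehot)
    w_dice, w_ce = cfg.loss_weights
    if cfg.loss == "dice":
        w_ce = 0.0
    elif cfg.loss == "ce":
        w_dice = 0.0
    n = float(target.size)
    total = Tensor(0.0)
    if w_ce:
        clipped = probs * Tensor(np.float32(1 - 1e-6)) + Tensor(np.float32(1e-7))
        total = total + Tensor(np.float32(-w_ce / n)) * ad.vsum(t * ad.log(clipped))
    if w_dice:
        # mean soft Dice loss over foreground classes
        fg = range(1, num_classes)
        for c in fg:
            pc = Tensor(probs.data[c], parents=((probs, _take_channel_back(c, probs.shape)),))
            tc = Tensor(onehot[c])
            inter = ad.vsum(pc * tc)
            denom = ad.vsum(pc) + Tensor(np.float32(onehot[c].sum()))
            dice = (Tensor(np.float32(2.0)) * inter + Tensor(np.float32(_EPS))) / (
                denom + Tensor(np.float32(_EPS))
            )
            total = total + Tensor(np.float32(w_dice / len(fg))) * (Tensor(np.float32(1.0)) - dice)
    return total


def _take_channel_back(c, shape):
    def back(g):
        out = np.zeros(shape, dtype=np.float32)
        out[c] = g
        return out

    return back


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(mask)
    return mask & ~er


def hausdorff_masks(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Symmetric Hausdorff distance (mm) between the surface voxels of two
    binary masks."""
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(_surface_voxels(a.astype(bool))) * spacing
    pb = np.argwhere(_surface_voxels(b.astype(bool))) * spacing
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def evaluate(pred: Mask | np.ndarray, truth: Mask | np.ndarray, spacing=None):
    """(Dice %, cross-entropy, Hausdorff mm) of a predicted mask against the
    ground truth.  ``pred`` may be a hard mask or a foreground-probability
    volume (thresholded at 0.5 for the geometric metrics)."""
    if isinstance(pred, (Mask, Volume)):
        spacing = pred.spacing if spacing is None else spacing
        pred = pred.data
    if isinstance(truth, (Mask, Volume)):
        spacing = truth.spacing if spacing is None else spacing
        truth = truth.data
    spacing = np.ones(3) if spacing is None else np.asarray(spacing, dtype=float)
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between prediction and truth")
    hard = pred >= 0.5
    t = truth.astype(bool)
    if not hard.any() and not t.any():
        raise MetricError("both masks are empty; metrics undefined")
    ce = ce_loss(np.clip(pred, 0.0, 1.0), t.astype(np.uint8))
    dice_pct = 100.0 * (1.0 - dice_loss(hard.astype(float), t.astype(float)))
    if not hard.any() or not t.any():
        hd = float("inf")
    else:
        hd = hausdorff_masks(hard, t, spacing)
    return dice_pct, ce, hd


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

#: documented parameter ranges of the five on-the-fly transforms
AUGMENT_RANGES = {
    "rotation_deg": 15.0,
    "translation_vox": 10,
    "contrast_gamma": (0.7, 1.5),
    "elastic_max_vox": 4.0,
}

_ALL_TRANSFORMS = ("rotation", "flip", "contrast", "translation", "elastic")


def flip_lr(image: np.ndarray) -> np.ndarray:
    """Left-right (sagittal-axis, first-axis) flip; an involution."""
    return image[::-1, :, :].copy()


def augment(
    image: Volume | np.ndarray,
    mask: Mask | np.ndarray,
    seed: int,
    transforms: tuple[str, ...] = _ALL_TRANSFORMS,
    probability: float = 0.5,
):
    """One randomly parameterized composition of 3D rotation, horizontal
    flip, contrast (gamma), integer translation and elastic deformation.

    The same geometric transform is applied to image and mask; the mask is
    resampled with nearest-neighbor interpolation so it stays binary.
    Deterministic for a fixed seed.
    """
    img = np.asarray(image.data if isinstance(image, Volume) else image, dtype=float)
    msk = np.asarray(mask.data if isinstance(mask, Mask) else mask)
    rng = np.random.default_rng(seed)
    for name in transforms:
        if name not in _ALL_TRANSFORMS:
            raise ConfigError(f"unknown transform {name!r}")
        apply = rng.random() < probability
        if name == "rotation":
            angle = rng.uniform(-AUGMENT_RANGES["rotation_deg"], AUGMENT_RANGES["rotation_deg"])
            axes = tuple(sorted(rng.choice(3, size=2, replace=False)))
            if apply:
                img = ndimage.rotate(img, angle, axes=axes, reshape=False, order=1, mode="nearest")
                msk = ndimage.rotate(msk, angle, axes=axes, reshape=False, order=0, mode="nearest")
        elif name == "flip":
            if apply:
                img, msk = flip_lr(img), flip_lr(msk)
        elif name == "contrast":
            gamma = rng.uniform(*AUGMENT_RANGES["contrast_gamma"])
            if apply:
                lo, hi = img.min(), img.max()
                if hi > lo:
                    img = (np.clip((img - lo) / (hi - lo), 0, 1) ** gamma) * (hi - lo) + lo
        elif name == "translation":
            t = AUGMENT_RANGES["translation_vox"]
            shift = rng.integers(-t, t + 1, size=3)
            if apply:
                img = ndimage.shift(img, shift, order=0, mode="nearest")
                msk = ndimage.shift(msk, shift, order=0, mode="nearest")
        elif name == "elastic":
            amp = AUGMENT_RANGES["elastic_max_vox"]
            disp = [ndimage.gaussian_filter(rng.normal(size=img.shape), 4) for _ in range(3)]
            if apply:
                disp = [d / max(np.abs(d).max(), 1e-9) * amp for d in disp]
                coords = np.indices(img.shape, dtype=float)
                warped = [c + d for c, d in zip(coords, disp)]
                img = ndimage.map_coordinates(img, warped, order=1, mode="nearest")
                msk = ndimage.map_coordinates(msk, warped, order=0, mode="nearest")
    msk = (np.asarray(msk) > 0.5).astype(np.uint8) if msk.dtype != np.uint8 else msk
    if isinstance(image, Volume):
        return Volume(img, image.spacing.copy(), image.origin.copy()), Mask(
            msk, mask.spacing.copy(), mask.origin.copy()
        )
    return img, msk


# ---------------------------------------------------------------------------
# training loop and cross-validation
# ---------------------------------------------------------------------------

def train_model(
    model: SegmentationModel,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    augment_data: bool = False,
):
    """Train with Adam on (image, label) patches; returns the model and the
    per-epoch mean training loss.  ``epochs == 0`` leaves the model
    untouched.  Seeded and reproducible."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    dataset = [
        (
            np.asarray(img.data if isinstance(img, Volume) else img, dtype=np.float32),
            np.asarray(m.data if isinstance(m, Mask) else m),
        )
        for img, m in dataset
    ]
    opt = Adam(
        model.parameters,
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for step, idx in enumerate(order):
            img, lab = dataset[idx]
            if augment_data:
                img, lab = augment(img, lab, seed=int(rng.integers(2**31)))
                img = img.astype(np.float32)
            loss = _loss_tensor(model.logits(img), lab, cfg)
            val = float(loss.data)
            if not np.isfinite(val):
                raise DivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            if (step + 1) % cfg.batch_size == 0 or step == len(order) - 1:
                opt.step()
                opt.zero_grad()
            losses.append(val)
        history.append(float(np.mean(losses)))
    return model, history


def cross_validate(
    cohort: list[dict],
    cfg: TrainConfig,
    net_cfg: NetworkConfig,
    eval_class: int = 1,
) -> pd.DataFrame:
    """Patient-wise k-fold cross-validation.

    ``cohort`` is a list of patients, each a dict with ``patient_id`` and
    ``samples`` -- a list of (image, label) patches (e.g. both joints of the
    patient).  Folds partition patients; all patches of a validation patient
    are excluded from training.  Returns a table with per-fold mean +- sd of
    Dice (%), cross-entropy and Hausdorff distance for ``eval_class``.
    """
    if len(cohort) < cfg.folds:
        raise ConfigError(
            f"need at least folds={cfg.folds} patients, got {len(cohort)}"
        )
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    rows = []
    for fold, (train_idx, val_idx) in enumerate(kf.split(cohort)):
        train_set = [s for i in train_idx for s in cohort[i]["samples"]]
        model = build_model(net_cfg, seed=cfg.seed + fold)
        model, _ = train_model(model, train_set, cfg)
        metrics = {"DICE": [], "CE": [], "HD": []}
        for i in val_idx:
            for img, lab in cohort[i]["samples"]:
                img = np.asarray(img.data if isinstance(img, Volume) else img)
                lab = np.asarray(lab.data if isinstance(lab, Mask) else lab)
                probs = model.predict_proba(img)
                pred_fg = probs[eval_class]
                truth = (lab == eval_class).astype(np.uint8)
                d, c, h = evaluate(pred_fg, truth, spacing=np.ones(3))
                metrics["DICE"].append(d)
                metrics["CE"].append(c)
                metrics["HD"].append(h)
        for score, vals in metrics.items():
            rows.append(
                {
                    "fold": fold,
                    "score": score,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals)),
                    "n_val_patients": len(val_idx),
                    "val_patients": sorted(int(cohort[i]["patient_id"]) for i in val_idx),
                }
            )
    return pd.DataFrame(rows)


def metrics_table(results: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Flatten {object: {architecture: fold table}} into the (object, score,
    architecture, mean, sd) layout used for reporting."""
    rows = []
    for obj, by_arch in results.items():
        for arch, table in by_arch.items():
            for score in ("DICE", "CE", "HD"):
                sub = table[table["score"] == score]
                rows.append(
                    {
                        "object": obj,
                        "score": score,
                        "architecture": arch,
                        "mean": float(sub["mean"].mean()),
                        "sd": float(sub["mean"].std(ddof=0)),
                    }
                )
    return pd.DataFrame(rows)
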