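"""Coarse joint localization and left/right VOI extraction.

Localization is treated as segmentation at a reduced resolution: the head
volume is resampled to a small grid, a (toy-trainable) network produces a
joint-probability field, the field is thresholded by the histogram
*minimum method* (valley between the two dominant modes, found on a
moving-average-smoothed histogram -- the classical iterated-smoothing
scheme), cleaned up morphologically, and the two largest connected
components become the left and right volume-of-interest bounding boxes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, LocalizationError
from .io_formats import Mask, Volume
from .nets import SegmentationModel

logger = logging.getLogger("negvol")

#: default low-resolution grid for localization
LOCALIZATION_SHAPE = (160, 160, 160)


@dataclass
class BoundingBox:
    """Half-open voxel-index box ``[min_index, max_index)`` on a grid."""

    min_index: np.ndarray
    max_index: np.ndarray
    side: str = ""

    def __post_init__(self):
        self.min_index = np.asarray(self.min_index, dtype=int)
        self.max_index = np.asarray(self.max_index, dtype=int)
        if not np.all(self.min_index < self.max_index):
            raise ValueError(
                f"degenerate box: min {self.min_index} !< max {self.max_index}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.max_index - self.min_index)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(int(a), int(b)) for a, b in zip(self.min_index, self.max_index))

    def to_dict(self) -> dict:
        return {
            "min_index": self.min_index.tolist(),
            "max_index": self.max_index.tolist(),
            "side": self.side,
        }


def coarse_segment(v: Volume, model: SegmentationModel) -> Volume:
    """Per-voxel joint probability at the localization resolution: the
    model's total foreground probability, guaranteed in [0, 1]."""
    probs = model.predict_proba(v.data)
    fg = probs[1:].sum(axis=0)
    return Volume(np.clip(fg, 0.0, 1.0), v.spacing.copy(), v.origin.copy())


def minimum_threshold(values: np.ndarray, bins: int = 256, max_smooth: int = 10000) -> float:
    """Histogram threshold by the minimum method.

    The histogram is smoothed with a 3-tap moving average, repeatedly, until
    exactly two local maxima remain; the threshold is the deepest valley
    between them (when the minimum is a flat plateau, its middle bin -- the
    natural tie-break for a threshold).  Returns ``nan`` if the histogram
    never becomes bimodal (constant or strictly unimodal data).
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=bins)
    h = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(3) / 3.0
    for _ in range(max_smooth):
        maxima = _local_maxima(h)
        if len(maxima) == 2:
            lo, hi = maxima
            seg = h[lo: hi + 1]
            ties = np.flatnonzero(seg == seg.min())
            valley = lo + int(ties[len(ties) // 2])
            return float(centers[valley])
        if len(maxima) < 2:
            return float("nan")
        h = np.convolve(h, kernel, mode="same")
    return float("nan")


def _local_maxima(h: np.ndarray) -> list[int]:
    """Indices of strict plateau-aware local maxima of a 1D histogram."""
    maxima = []
    n = len(h)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left = h[i - 1] if i > 0 else -np.inf
        right = h[j + 1] if j + 1 < n else -np.inf
        if h[i] > left and h[i] > right and h[i] > 0:
            maxima.append(i + (j - i) // 2)
        i = j + 1
    return maxima


def postprocess_localization(
    p: Volume,
    opening_radius: int = 1,
    min_component_frac: float = 0.1,
) -> Mask:
    """Threshold a probability field (minimum method, falling back to 0.5
    when the histogram is unimodal) and remove morphological outliers.

    The output is always a subset of the raw thresholded mask: opening and
    small-component removal only delete voxels.
    """
    data = np.asarray(p.data, dtype=float)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("probability volume must lie in [0, 1]")
    tau = minimum_threshold(data)
    if not np.isfinite(tau):
        warnings.warn(
            "probability histogram is unimodal; falling back to threshold 0.5",
            stacklevel=2,
        )
        tau = 0.5
    mask = data > tau
    if not mask.any():
        warnings.warn("localization produced an empty mask", stacklevel=2)
        return Mask(mask.astype(np.uint8), p.spacing.copy(), p.origin.copy())
    if opening_radius > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_opening(mask, struct, iterations=opening_radius)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_frac * sizes.max()) + 1
        mask = np.isin(labels, keep)
    return Mask(mask.astype(np.uint8), p.spacing.copy(), p.origin.copy())


def extract_voi_boxes(
    m: Mask,
    margin_frac: float = 0.1,
    full_shape: tuple[int, int, int] | None = None,
) -> tuple[BoundingBox, BoundingBox]:
    """Tight boxes of the two largest components, padded by ``margin_frac``
    per axis and labeled left/right by centroid position relative to the
    mid-sagittal plane (x midline).  If ``full_shape`` is given the indices
    are rescaled from the localization grid to that grid."""
    labels, n = ndimage.label(m.data.astype(bool))
    if n < 2:
        raise LocalizationError(
            f"expected two joint components (one per body side), found {n}"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    top2 = np.argsort(sizes)[-2:] + 1
    shape = np.array(m.data.shape)
    boxes = []
    for lab in top2:
        idx = np.nonzero(labels == lab)
        lo = np.array([int(i.min()) for i in idx])
        hi = np.array([int(i.max()) + 1 for i in idx])
        pad = np.ceil((hi - lo) * margin_frac).astype(int)
        lo = np.maximum(lo - pad, 0)
        hi = np.minimum(hi + pad, shape)
        cx = float(np.mean(idx[0]))
        boxes.append((cx, lo, hi))
    boxes.sort(key=lambda b: b[0])
    mid = shape[0] / 2.0
    (cx_l, lo_l, hi_l), (cx_r, lo_r, hi_r) = boxes
    if cx_l >= mid and cx_r >= mid:
        logger.warning("both joint components lie on the same side of the midline")
    if full_shape is not None:
        scale = np.array(full_shape) / shape
        lo_l = np.floor(lo_l * scale).astype(int)
        hi_l = np.minimum(np.ceil(hi_l * scale), full_shape).astype(int)
        lo_r = np.floor(lo_r * scale).astype(int)
        hi_r = np.minimum(np.ceil(hi_r * scale), full_shape).astype(int)
    return (
        BoundingBox(lo_l, hi_l, side="left"),
        BoundingBox(lo_r, hi_r, side="right"),
    )


def crop_voi(v: Volume, b: BoundingBox, patch_shape: tuple[int, int, int] | None = None) -> Volume:
    """Crop the box out of a volume (origin shifted accordingly).

    With ``patch_shape`` the crop window is re-centered on the box and
    resized to exactly that shape, *using real volume data* wherever the
    window stays inside the grid (the window slides back inside when it
    would overhang); only where the grid itself is smaller than the patch is
    the result zero-padded symmetrically."""
    shape = np.array(v.data.shape)
    if np.any(b.min_index < 0) or np.any(b.max_index > shape):
        raise IndexError(f"box {b.min_index}..{b.max_index} outside grid {tuple(shape)}")
    if patch_shape is None:
        data = v.data[b.slices()]
        return Volume(data, v.spacing.copy(), v.origin + b.min_index * v.spacing)
    patch = np.asarray(patch_shape, dtype=int)
    center = (b.min_index + b.max_index) / 2.0
    lo = np.round(center - patch / 2.0).astype(int)
    lo = np.clip(lo, 0, np.maximum(shape - patch, 0))  # slide inside the grid
    take = np.minimum(patch, shape)
    src = tuple(slice(int(a), int(a + n)) for a, n in zip(lo, take))
    out = np.zeros(tuple(patch), dtype=v.data.dtype)
    dst_lo = (patch - take) // 2
    dst = tuple(slice(int(a), int(a + n)) for a, n in zip(dst_lo, take))
    out[dst] = v.data[src]
    origin = v.origin + (lo - dst_lo) * v.spacing
    return Volume(out, v.spacing.copy(), origin)


def embed_mask(mask_data: np.ndarray, b: BoundingBox, full_shape, crop_origin_shift=None) -> np.ndarray:
    """Place a VOI-space mask back into a full grid (inverse of crop_voi for
    boxes that were not re-centered)."""
    out = np.zeros(tuple(full_shape), dtype=np.uint8)
    out[b.slices()] = mask_data[: b.shape[0], : b.shape[1], : b.shape[2]]
    return out


def box_corner_mse(predicted: BoundingBox, truth: BoundingBox) -> float:
    """Mean squared error between the 2x3 corner index vectors of two boxes
    (low-resolution voxel units)."""
    p = np.concatenate([predicted.min_index, predicted.max_index]).astype(float)
    t = np.concatenate([truth.min_index, truth.max_index]).astype(float)
    return float(np.mean((p - t) ** 2))
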