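"""Classical image-processing route for the socket bone and slice-stack
smoothing ahead of 3D reconstruction.

The socket ("temporal") bone has many fine irregularities and is the
harder of the two bones to segment with a network trained on few
annotations, so a deterministic classical chain complements the learned
heatmap: denoise, threshold to candidate bone, close edges, smooth
morphologically, detect edges (per-slice Canny with cross-slice linking, or
a 3D gradient-magnitude alternative), fill, and drop small components.  The
result is then *fused* with the network's fossa heatmap:

    fused = (classical AND dilate(heatmap >= tau)) OR (heatmap >= tau_core)

-- the classical detail is trusted only where the network roughly agrees,
and the network's confident core is always kept.  The fusion rule and all
stage parameters are configuration, not anatomy; the rule itself is one of
several reasonable readings of "fused" and is documented as such.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, morphology

from .errors import ConfigError
from .io_formats import Mask, Volume


@dataclass
class EnhanceParams:
    """Stage parameters of the classical route (all config-exposed)."""

    median_size: int = 3  # denoising median kernel (voxels)
    threshold: float = 0.6  # candidate-bone intensity (volume normalized to [0,1])
    #: edge-closing radius (voxels); must stay below half the joint-space
    #: width or closing bridges the gap between the two bones
    closing_radius: int = 1
    opening_radius: int = 1  # erosion/dilation smoothing
    canny_sigma: float = 1.0
    edge_mode: str = "canny2d"  # per-slice Canny + cross-slice link, or "grad3d"
    min_component_vox: int = 64
    #: only enclosed cavities up to this fraction of the bone volume are
    #: filled; the joint space itself is an enclosed cavity and must not be
    max_fill_hole_frac: float = 0.1
    fuse_tau: float = 0.5
    fuse_tau_core: float | None = None  # defaults to fuse_tau
    fuse_dilate_radius: int = 3


def classical_tb_mask(v: Volume, params: EnhanceParams | None = None) -> Mask:
    """Deterministic classical segmentation of the socket bone in a
    normalized VOI.

    Stage order: median denoise -> intensity threshold -> morphological
    closing -> opening (erosion/dilation smoothing) -> edge detection
    (per-slice Canny linked across slices, or 3D gradient magnitude) ->
    boundary fill -> small-component removal.
    """
    p = params or EnhanceParams()
    data = np.asarray(v.data, dtype=float)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("classical route expects a volume normalized to [0, 1]")
    if data.max() - data.min() < 1e-12:
        warnings.warn("flat volume; classical route returns an empty mask", stacklevel=2)
        return Mask(np.zeros(data.shape, np.uint8), v.spacing.copy(), v.origin.copy())

    den = ndimage.median_filter(data, size=p.median_size)
    candidate = den > p.threshold
    if p.closing_radius > 0:
        candidate = ndimage.binary_closing(
            candidate, morphology.ball(p.closing_radius)
        )
    if p.opening_radius > 0:
        candidate = ndimage.binary_opening(
            candidate, morphology.ball(p.opening_radius)
        )

    if p.edge_mode == "canny2d":
        edges = np.zeros_like(candidate)
        for k in range(data.shape[2]):
            edges[:, :, k] = feature.canny(den[:, :, k], sigma=p.canny_sigma)
        # link edges across slices: close along z so per-slice contours join
        edges = ndimage.binary_closing(edges, np.ones((1, 1, 3), bool))
    elif p.edge_mode == "grad3d":
        grad = ndimage.gaussian_gradient_magnitude(den, sigma=p.canny_sigma)
        edges = grad > np.percentile(grad, 90)
    else:
        raise ConfigError(f"unknown edge_mode {p.edge_mode!r}")
    # edges refine the candidate boundary: keep them only near the candidate
    # and at bone-like intensity -- in a thin joint the gradient maximum sits
    # mid-gap, and those soft-tissue edge voxels must not enter the bone mask
    near = ndimage.binary_dilation(candidate, iterations=2)
    bone_like = den >= 0.9 * p.threshold
    mask = _fill_small_holes(candidate | (edges & near & bone_like), p.max_fill_hole_frac)

    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= p.min_component_vox) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        warnings.warn("classical route produced an empty mask", stacklevel=2)
    return Mask(mask.astype(np.uint8), v.spacing.copy(), v.origin.copy())


def _fill_small_holes(mask: np.ndarray, max_frac: float) -> np.ndarray:
    """Fill enclosed background cavities no larger than ``max_frac`` of the
    foreground volume (unlike a plain fill, large anatomical cavities --
    the joint space -- stay open)."""
    labels, n = ndimage.label(~mask)
    if n == 0:
        return mask
    out = mask.copy()
    limit = max_frac * max(int(mask.sum()), 1)
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    for lab in range(1, n + 1):
        if lab not in border_labels and sizes[lab - 1] <= limit:
            out[labels == lab] = True
    return out


def fuse_with_heatmap(
    classical: Mask,
    fossa_heatmap: Volume | np.ndarray,
    tau: float = 0.5,
    tau_core: float | None = None,
    dilate_radius: int = 3,
) -> Mask:
    """Fuse the classical mask with the network's fossa heatmap.

    ``fused = (classical AND dilate(heatmap >= tau, r)) OR (heatmap >= tau_core)``,
    so the output always contains the heatmap core and never exceeds
    ``classical OR core``.  Monotone in ``tau``: raising it never grows the
    output.
    """
    if not 0 < tau < 1:
        raise ConfigError(f"tau must be in (0, 1), got {tau}")
    tau_core = tau if tau_core is None else tau_core
    if not 0 < tau_core < 1:
        raise ConfigError(f"tau_core must be in (0, 1), got {tau_core}")
    heat = np.asarray(
        fossa_heatmap.data if isinstance(fossa_heatmap, Volume) else fossa_heatmap,
        dtype=float,
    )
    cls = classical.data.astype(bool)
    if heat.shape != cls.shape:
        raise ValueError("heatmap and classical mask shapes differ")
    agree = heat >= tau
    if dilate_radius > 0 and agree.any():
        agree = ndimage.binary_dilation(agree, iterations=dilate_radius)
    core = heat >= tau_core
    fused = (cls & agree) | core
    return Mask(fused.astype(np.uint8), classical.spacing.copy(), classical.origin.copy())


def smooth_stack(
    m: Mask,
    spacing=None,
    irregularity_mm: float = 1.0,
    target_pitch: float = 0.4,
    max_volume_change_frac: float = 0.1,
) -> Mask:
    """Slice-stack smoothing feeding surface reconstruction.

    Slice-wise 2D median filtering with the radius matched to the
    irregularity scale, then inter-slice interpolation to the reconstruction
    pitch (default 0.4 mm).  Warns if the physical mask volume changes by
    more than ``max_volume_change_frac``.
    """
    spacing = np.asarray(m.spacing if spacing is None else spacing, dtype=float)
    data = m.data.astype(bool)
    if not data.any():
        raise ValueError("smooth_stack needs a non-empty mask")
    radius = max(1, int(round(irregularity_mm / float(spacing[:2].min()))))
    size = 2 * radius + 1
    if size > min(data.shape[:2]):
        raise ConfigError(
            f"median radius {radius} vox exceeds the slice extent {data.shape[:2]}"
        )
    sm = ndimage.median_filter(data.astype(np.uint8), size=(size, size, 1)) > 0

    zoom_z = float(spacing[2]) / float(target_pitch)
    if abs(zoom_z - 1.0) > 1e-6:
        sm_f = ndimage.zoom(sm.astype(float), (1.0, 1.0, zoom_z), order=1)
        sm = sm_f > 0.5
    out_spacing = np.array([spacing[0], spacing[1], target_pitch])
    before = float(data.sum()) * float(np.prod(spacing))
    after = float(sm.sum()) * float(np.prod(out_spacing))
    if before > 0 and abs(after - before) / before > max_volume_change_frac:
        warnings.warn(
            f"smoothing changed the mask volume by "
            f"{100 * abs(after - before) / before:.1f}%",
            stacklevel=2,
        )
    return Mask(sm.astype(np.uint8), out_spacing, m.origin.copy())
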