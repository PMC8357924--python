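"""Synthetic ball-and-socket joint phantoms with analytically known joint space.

The phantom emulates the anatomy the pipeline targets: a dense condyle
("ball" of radius ``r`` with a cylindrical neck) articulating in a
hemispherical socket ("fossa") of radius ``r + g`` carved into a slab bone,
leaving a uniform joint-space gap of thickness ``g``.  The *negative volume*
of this geometry -- the empty shell between ball and socket above the
equatorial plane -- has the closed form

    V_neg = (2/3) * pi * [(r + g)^3 - r^3]        (mm^3)

and its surface area (outer dome + inner dome + equatorial annulus)

    S_neg = 2*pi*(r + g)^2 + 2*pi*r^2 + pi*[(r + g)^2 - r^2]   (mm^2),

so every pipeline stage can be scored against ground truth without the
private CT cohort the method was developed on.  Left/right pairs share one
mid-sagittal mirror plane; ``asymmetry_factor`` scales the right-side gap,
which changes both closed forms and lets symmetry metrics be validated on
constructed pathology.

Intensities are three plateaus (bone / soft tissue / air) plus additive
Gaussian noise -- the simplest model that exercises denoising, thresholding
and edge detection with a controllable SNR.  No trabecular texture, articular
disc, or CT physics (beam hardening, HU calibration) is simulated.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PhantomSpecError
from .io_formats import Mask, TriMesh, Volume, mask_to_mesh, write_mesh, write_volume

#: default half-grid for one joint, voxels (x, y, z)
_JOINT_SHAPE = (48, 48, 64)


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic joint (all mm)."""

    condyle_radius: float = 6.0
    gap: float = 2.0
    neck_radius: float = 2.5
    neck_length: float = 8.0
    slab_thickness: float = 5.0  # bone above the fossa dome
    intensity_bone: float = 1000.0
    intensity_soft: float = 300.0
    intensity_air: float = 0.0
    noise_sd: float = 30.0
    asymmetry_factor: float = 1.0  # scales the right-side gap
    grid_shape: tuple[int, int, int] = _JOINT_SHAPE
    spacing: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.gap <= 0:
            raise PhantomSpecError("gap must be > 0")
        if self.condyle_radius <= self.neck_radius:
            raise PhantomSpecError("condyle_radius must exceed neck_radius")
        if self.asymmetry_factor <= 0:
            raise PhantomSpecError("asymmetry_factor must be > 0")
        if self.spacing <= 0:
            raise PhantomSpecError("spacing must be > 0")

    def side_gap(self, side: str) -> float:
        return self.gap * (self.asymmetry_factor if side == "right" else 1.0)

    def analytic_negative_volume(self, side: str = "left") -> float:
        r, rg = self.condyle_radius, self.condyle_radius + self.side_gap(side)
        return (2.0 / 3.0) * np.pi * (rg**3 - r**3)

    def analytic_negative_area(self, side: str = "left") -> float:
        r, rg = self.condyle_radius, self.condyle_radius + self.side_gap(side)
        return 2 * np.pi * (rg**2 + r**2) + np.pi * (rg**2 - r**2)


@dataclass
class PhantomSample:
    """One synthetic joint with its ground truth."""

    volume: Volume
    mc_mask: Mask  # condyle ("mandibular condyle" analogue)
    tb_mask: Mask  # socket bone ("temporal bone" analogue)
    mc_mesh: TriMesh
    tb_mesh: TriMesh
    analytic_negative_volume: float  # mm^3
    analytic_negative_area: float  # mm^2
    side: str
    condyle_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    clip_plane: tuple[np.ndarray, np.ndarray] | None = None  # (point, normal), mm
    spec: PhantomSpec | None = None


def _joint_masks(spec: PhantomSpec, side: str):
    """Binary condyle and socket-bone masks on the joint grid, plus geometry."""
    sp = float(spec.spacing)
    shape = tuple(int(s) for s in spec.grid_shape)
    extent = np.array(shape) * sp
    r = spec.condyle_radius
    g = spec.side_gap(side)
    rg = r + g
    margin = 2 * sp

    # ball center: lateral center; vertically leave room for the neck below
    # and the fossa dome plus roof above.
    cz = margin + spec.neck_length + r
    top = cz + rg + spec.slab_thickness
    c = np.array([extent[0] / 2, extent[1] / 2, cz])
    if top + margin > extent[2]:
        raise PhantomSpecError(
            f"joint (height {top + margin:.1f} mm) does not fit grid "
            f"z-extent {extent[2]:.1f} mm"
        )
    if rg + 1.5 + margin > extent[0] / 2 or rg + 1.5 + margin > extent[1] / 2:
        raise PhantomSpecError("fossa radius does not fit grid laterally")

    xs = (np.arange(shape[0]) + 0.5) * sp
    ys = (np.arange(shape[1]) + 0.5) * sp
    zs = (np.arange(shape[2]) + 0.5) * sp
    X, Y, Z = np.meshgrid(xs - c[0], ys - c[1], zs - c[2], indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    rho = np.sqrt(X**2 + Y**2)

    ball = dist <= r
    neck = (rho <= spec.neck_radius) & (Z <= 0) & (Z >= -(r + spec.neck_length))
    mc = ball | neck
    # the slab is laterally bounded so two mirrored joints in one head stay
    # disconnected at the midline
    slab_halfwidth = rg + 1.5
    tb = (
        (Z >= 0)
        & (Z <= rg + spec.slab_thickness)
        & (dist >= rg)
        & (np.maximum(np.abs(X), np.abs(Y)) <= slab_halfwidth)
    )
    cavity = (dist < rg) & ~mc  # joint space + below-equator soft pocket
    soft = cavity & (Z >= -g)
    return mc, tb, soft, c


def make_joint_phantom(spec: PhantomSpec, side: str = "left") -> PhantomSample:
    """Generate one joint phantom with volume, masks, meshes and closed-form
    negative-volume truth.  Deterministic for a fixed spec/seed."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    mc, tb, soft, c = _joint_masks(spec, side)
    sp = float(spec.spacing)
    data = np.full(mc.shape, float(spec.intensity_air))
    data[soft] = spec.intensity_soft
    data[mc | tb] = spec.intensity_bone
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + (1 if side == "right" else 0))
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    spacing = np.full(3, sp)
    vol = Volume(data, spacing)
    mc_mask = Mask(mc.astype(np.uint8), spacing)
    tb_mask = Mask(tb.astype(np.uint8), spacing)
    return PhantomSample(
        volume=vol,
        mc_mask=mc_mask,
        tb_mask=tb_mask,
        mc_mesh=mask_to_mesh(mc_mask),
        tb_mesh=mask_to_mesh(tb_mask),
        analytic_negative_volume=spec.analytic_negative_volume(side),
        analytic_negative_area=spec.analytic_negative_area(side),
        side=side,
        condyle_center=c,
        clip_plane=(c.copy(), np.array([0.0, 0.0, 1.0])),
        spec=spec,
    )


@dataclass
class HeadPhantom:
    """A two-joint "head" volume with per-side ground truth."""

    volume: Volume
    samples: dict  # side -> PhantomSample (coordinates local to the side crop)
    boxes: dict  # side -> (min_index, max_index), half-open voxel coords
    spec: PhantomSpec
    metadata: dict = field(default_factory=dict)


def make_head_phantom(spec: PhantomSpec) -> HeadPhantom:
    """Embed a left and a mirrored right joint in one volume.

    The joints are mirror images about the mid-sagittal grid plane
    ``x = nx * spacing`` (``nx`` = per-joint grid width); for
    ``asymmetry_factor == 1`` the reflection is exact.
    """
    left = make_joint_phantom(spec, "left")
    right = make_joint_phantom(spec, "right")
    nx = spec.grid_shape[0]
    shape = (2 * nx, spec.grid_shape[1], spec.grid_shape[2])
    spacing = np.full(3, float(spec.spacing))

    def mirror(a):  # right half is the x-flip of the right joint's own grid
        return a[::-1, :, :]

    data = np.concatenate([left.volume.data, mirror(right.volume.data)], axis=0)
    head = Volume(data, spacing)

    boxes = {}
    for side, sample in (("left", left), ("right", right)):
        bone = sample.mc_mask.data.astype(bool) | sample.tb_mask.data.astype(bool)
        if side == "right":
            bone = mirror(bone)
        idx = np.nonzero(bone)
        lo = np.array([int(i.min()) for i in idx])
        hi = np.array([int(i.max()) + 1 for i in idx])
        if side == "right":
            lo[0] += nx
            hi[0] += nx
        boxes[side] = (lo, hi)
    if boxes["left"][1][0] > boxes["right"][0][0]:
        raise PhantomSpecError("left and right joints overlap at the midline")
    meta = {
        "asymmetry_factor": spec.asymmetry_factor,
        "asymmetric": spec.asymmetry_factor != 1.0,
        "seed": spec.seed,
        "analytic_negative_volume": {
            s: spec.analytic_negative_volume(s) for s in ("left", "right")
        },
        "analytic_negative_area": {
            s: spec.analytic_negative_area(s) for s in ("left", "right")
        },
    }
    return HeadPhantom(
        volume=head,
        samples={"left": left, "right": right},
        boxes=boxes,
        spec=spec,
        metadata=meta,
    )


#: cohort parameter ranges a scaled-down study draws from; geometry varies a
#: few voxels around the defaults so bones differ across "patients"
DEFAULT_COHORT_RANGES = {
    "condyle_radius": (5.5, 6.5),
    "gap": (1.8, 2.2),
    "neck_radius": (2.2, 2.8),
}


def make_cohort(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    n_asymmetric: int = 0,
    asymmetry_range: tuple[float, float] = (1.2, 1.5),
    base_spec: PhantomSpec | None = None,
) -> list[HeadPhantom]:
    """Generate ``n`` head phantoms with parameters drawn uniformly from
    ``spec_ranges``; the last ``n_asymmetric`` get an asymmetry factor drawn
    from ``asymmetry_range`` (the rest are exactly symmetric) and are flagged
    ``asymmetric`` in their metadata.  Fully reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_asymmetric <= n:
        raise ValueError("n_asymmetric must be in [0, n]")
    ranges = dict(DEFAULT_COHORT_RANGES if spec_ranges is None else spec_ranges)
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise PhantomSpecError(f"empty range for {k}: ({lo}, {hi})")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        asym = i >= n - n_asymmetric
        af = float(rng.uniform(*asymmetry_range)) if asym else 1.0
        spec = dataclasses.replace(
            base, seed=seed + 1000 * (i + 1), asymmetry_factor=af, **params
        )
        head = make_head_phantom(spec)
        head.metadata["patient_id"] = i
        cohort.append(head)
    return cohort


def save_head_phantom(head: HeadPhantom, directory: str | Path) -> Path:
    """Write a head phantom as NIfTI + STL + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(head.volume, directory / "head.nii.gz")
    for side, sample in head.samples.items():
        write_mesh(sample.mc_mesh, directory / f"{side}_condyle.stl")
        write_mesh(sample.tb_mesh, directory / f"{side}_socket.stl")
        write_volume(
            Volume(sample.mc_mask.data, sample.mc_mask.spacing),
            directory / f"{side}_condyle_mask.nii.gz",
        )
        write_volume(
            Volume(sample.tb_mask.data, sample.tb_mask.spacing),
            directory / f"{side}_socket_mask.nii.gz",
        )
    meta = dict(head.metadata)
    meta["boxes"] = {s: [lo.tolist(), hi.tolist()] for s, (lo, hi) in head.boxes.items()}
    meta["spec"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(head.spec).items()
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory
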