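"""Volumes, masks and triangle meshes: reading, writing and conversions.

The in-memory containers are deliberately small:

* :class:`Volume` -- a 3D scalar grid with physical voxel spacing (mm) and a
  world origin.  Axis order is ``(x, y, z)`` with axial slices stacked along
  ``z``.  A voxel with index ``i`` occupies the half-open cube
  ``[origin + i * spacing, origin + (i + 1) * spacing)`` and its *center* sits
  at ``origin + (i + 0.5) * spacing``.
* :class:`Mask` -- a binary grid aligned with its parent volume.
* ``TriMesh`` -- an alias for :class:`trimesh.Trimesh`; all meshes live in mm
  world coordinates.

Conversions between the voxel and the mesh worlds are `voxelize_mesh`
(solid rasterization by an exact voxel-center parity test) and `mask_to_mesh`
(marching cubes on the 0.5-isosurface).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import trimesh
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.transform import resize as _sk_resize

from .errors import FormatError, GeometryError, ResourceError

TriMesh = trimesh.Trimesh

#: refuse to allocate resampled volumes above this many voxels
MAX_VOXELS = 2**30

_SLICE_PITCH_TOL = 1e-3  # mm


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; arbitrary units before normalization,
        dimensionless in [0, 1] after :func:`minmax_normalize`.
    spacing : 3-vector, mm per axis.
    origin : 3-vector, mm position of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin[a] + (np.arange(self.data.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class Mask:
    """A binary occupancy grid aligned with a :class:`Volume`."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError(f"Mask data must be 3D, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"Mask values must be 0/1, found {uniq[:10]}")
        self.data = data.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def copy(self) -> "Mask":
        return Mask(self.data.copy(), self.spacing.copy(), self.origin.copy())


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, format: str | None = None) -> Volume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    ``format`` is one of ``{"dicom-series", "nifti"}``; when omitted it is
    inferred: a directory is a DICOM series, a ``.nii``/``.nii.gz`` file is
    NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "dicom-series":
        return _read_dicom_series(path)
    if format == "nifti":
        return _read_nifti(path)
    raise FormatError(f"unknown volume format {format!r}")


def _read_nifti(path: Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return Volume(data, spacing, origin)


def _read_dicom_series(path: Path) -> Volume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    try:
        slices = [pydicom.dcmread(str(f)) for f in files]
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise FormatError(f"failed to read DICOM series in {path}: {exc}") from exc
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) < 2:
        raise FormatError("DICOM series needs at least two slices")
    gaps = np.diff(zs)
    pitch = np.median(gaps)
    bad = np.where(np.abs(gaps - pitch) > _SLICE_PITCH_TOL)[0]
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"non-uniform slice spacing: gap between slices {i} and {i + 1} is "
            f"{gaps[i]:.4f} mm, expected {pitch:.4f} mm"
        )
    first = slices[0]
    ps = [float(v) for v in first.PixelSpacing]  # (row, col) = (y, x)
    spacing = np.array([ps[1], ps[0], float(pitch)])
    # pixel_array is (rows, cols) = (y, x); stack to (x, y, z)
    data = np.stack([s.pixel_array.T for s in slices], axis=-1)
    ipp = [float(v) for v in first.ImagePositionPatient]
    origin = np.array([ipp[0], ipp[1], zs[0]])
    return Volume(data, spacing, origin)


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI; round-trips bit-identically through
    :func:`read_volume`."""
    path = Path(path)
    affine = np.diag(np.append(v.spacing, 1.0))
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(v.data, affine), str(path))
    return path


def write_dicom_series(v: Volume, directory: str | Path) -> Path:
    """Write a volume as one synthetic secondary-capture DICOM file per axial
    slice (int16 intensities).  Mainly used to exercise DICOM reading on
    generated data."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    data = np.round(v.data).astype(np.int16)
    for k in range(data.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = data.shape[1], data.shape[0]
        ds.PixelSpacing = [f"{v.spacing[1]:.8g}", f"{v.spacing[0]:.8g}"]
        ds.SliceThickness = f"{v.spacing[2]:.8g}"
        ds.ImagePositionPatient = [
            f"{v.origin[0]:.8g}",
            f"{v.origin[1]:.8g}",
            f"{v.origin[2] + k * v.spacing[2]:.8g}",
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = k + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(
            str(directory / f"slice_{k:04d}.dcm"),
            enforce_file_format=True,
        )
    return directory


def read_mesh(path: str | Path) -> TriMesh:
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):  # pragma: no cover - scene files
        raise FormatError(f"{path} does not contain a single triangle mesh")
    return mesh


def write_mesh(m: TriMesh, path: str | Path) -> Path:
    path = Path(path)
    m.export(str(path))
    return path


# ---------------------------------------------------------------------------
# intensity normalization and resampling
# ---------------------------------------------------------------------------

def minmax_normalize(v: Volume) -> Volume:
    """Min-max normalize intensities to [0, 1].

    A constant volume maps to all zeros (avoids division by zero).
    Idempotent: normalizing twice equals normalizing once.
    """
    data = np.asarray(v.data, dtype=float)
    if data.size == 0:
        raise FormatError("cannot normalize an empty volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite intensities")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return Volume(out, v.spacing.copy(), v.origin.copy())


def resample(v: Volume, target_shape, method: str = "trilinear") -> Volume:
    """Resample to ``target_shape`` preserving the physical extent.

    ``method`` is ``"trilinear"`` (default, isotropy-correct) or
    ``"bicubic-per-slice"`` -- bicubic in each axial plane plus linear along
    ``z``, the separable 3D reading of an in-plane bicubic resize.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 2 for s in target_shape):
        raise ValueError(f"target_shape must be 3 ints >= 2, got {target_shape}")
    if np.prod(target_shape, dtype=np.int64) > MAX_VOXELS:
        raise ResourceError(
            f"target shape {target_shape} exceeds the voxel budget {MAX_VOXELS}"
        )
    data = np.asarray(v.data, dtype=float)
    if method == "trilinear":
        out = _sk_resize(
            data, target_shape, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    elif method == "bicubic-per-slice":
        nz = data.shape[2]
        inplane = np.empty((target_shape[0], target_shape[1], nz))
        for k in range(nz):
            inplane[:, :, k] = _sk_resize(
                data[:, :, k], target_shape[:2], order=3, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
        out = _sk_resize(
            inplane, target_shape, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    scale = np.array(v.data.shape) / np.array(target_shape)
    return Volume(out, v.spacing * scale, v.origin.copy())


# ---------------------------------------------------------------------------
# mesh <-> mask conversions
# ---------------------------------------------------------------------------

def _boundary_edge_count(m: TriMesh) -> int:
    edges = m.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def voxelize_mesh(m: TriMesh, grid: Volume | Mask, subdivide: bool = True) -> Mask:
    """Rasterize a closed surface into the solid it bounds.

    A voxel is set iff its *center* lies inside the solid, decided by an exact
    ray-parity test along each ``z`` column (odd number of surface crossings
    above the center).  When ``subdivide`` is true the mesh edges are first
    split until shorter than the voxel spacing -- the classical refinement for
    rasterizing coarse annotation models; it leaves the surface, and hence
    the parity test, unchanged.
    """
    if not m.is_watertight:
        raise GeometryError(
            f"mesh is not watertight ({_boundary_edge_count(m)} boundary edges)"
        )
    spacing = np.asarray(grid.spacing, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    shape = grid.data.shape

    verts = np.asarray(m.vertices, dtype=float)
    faces = np.asarray(m.faces)
    if subdivide:
        max_edge = float(spacing.min())
        edge_vecs = verts[m.edges[:, 0]] - verts[m.edges[:, 1]]
        if edge_vecs.size and np.linalg.norm(edge_vecs, axis=1).max() > max_edge:
            verts, faces = trimesh.remesh.subdivide_to_size(
                verts, faces, max_edge=max_edge, max_iter=8
            )

    # voxel-center coordinates: center of voxel i is at index-coordinate i
    # after the transform below; the distinct per-axis epsilons avoid columns
    # passing exactly through triangle vertices or shared edges (ties would
    # break the parity count).
    eps = np.array([1.2345e-6, 2.7183e-6, 0.0])
    tv = (verts - origin) / spacing - 0.5 + eps

    inside = np.zeros(shape, dtype=bool)
    tris = tv[faces]  # (F, 3, 3)
    if tris.size == 0:
        return Mask(inside.astype(np.uint8), spacing, origin)

    # 2D bounding cells per triangle
    xy = tris[:, :, :2]
    lo = np.ceil(xy.min(axis=1)).astype(np.int64)
    hi = np.floor(xy.max(axis=1)).astype(np.int64)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(shape[:2]) - 1)
    w = hi[:, 0] - lo[:, 0] + 1
    h = hi[:, 1] - lo[:, 1] + 1
    valid = (w > 0) & (h > 0)
    if not np.any(valid):
        return Mask(inside.astype(np.uint8), spacing, origin)
    tri_idx = np.nonzero(valid)[0]
    cells = (w[valid] * h[valid]).astype(np.int64)

    # flattened (triangle, cell) pairs
    rep = np.repeat(tri_idx, cells)
    offs = np.arange(cells.sum()) - np.repeat(np.cumsum(cells) - cells, cells)
    wrep = np.repeat(w[valid], cells)
    px = np.repeat(lo[valid, 0], cells) + offs % wrep
    py = np.repeat(lo[valid, 1], cells) + offs // wrep

    a, b, c = tris[rep, 0], tris[rep, 1], tris[rep, 2]
    p = np.stack([px, py], axis=1).astype(float)
    d0 = (b[:, :2] - a[:, :2])
    d1 = (c[:, :2] - a[:, :2])
    d2 = p - a[:, :2]
    den = d0[:, 0] * d1[:, 1] - d1[:, 0] * d0[:, 1]
    ok = np.abs(den) > 1e-12
    u = np.where(ok, (d2[:, 0] * d1[:, 1] - d1[:, 0] * d2[:, 1]) / np.where(ok, den, 1), -1)
    vv = np.where(ok, (d0[:, 0] * d2[:, 1] - d2[:, 0] * d0[:, 1]) / np.where(ok, den, 1), -1)
    hit = ok & (u >= 0) & (vv >= 0) & (u + vv <= 1)
    if not np.any(hit):
        return Mask(inside.astype(np.uint8), spacing, origin)
    zc = a[hit, 2] + u[hit] * (b[hit, 2] - a[hit, 2]) + vv[hit] * (c[hit, 2] - a[hit, 2])
    cx, cy = px[hit], py[hit]

    # each crossing at height z toggles all voxels with center index k < z;
    # accumulate with a difference array along z and prefix-sum.
    nz = shape[2]
    diff = np.zeros((shape[0], shape[1], nz + 1), dtype=np.int64)
    kz = np.floor(zc).astype(np.int64) + 1  # first center not below the crossing
    keep = kz > 0
    kz = np.minimum(kz[keep], nz)
    np.add.at(diff, (cx[keep], cy[keep], np.zeros_like(kz)), 1)
    np.add.at(diff, (cx[keep], cy[keep], kz), -1)
    above = np.cumsum(diff[:, :, :-1], axis=2)
    inside = (above % 2) == 1
    return Mask(inside.astype(np.uint8), spacing, origin)


def mask_to_mesh(m: Mask, level: float = 0.5) -> TriMesh:
    """Extract the ``level``-isosurface of a binary mask as a watertight,
    outward-oriented triangle mesh in mm coordinates (marching cubes).

    Masks whose voxels touch only across edges or corners produce
    non-manifold isosurfaces; those are retried on a lightly Gaussian-
    smoothed occupancy field (symmetric kernel, so the surface position
    stays unbiased)."""
    data = m.data
    n_on = int(data.sum())
    if n_on == 0 or n_on == data.size:
        raise GeometryError("mask must contain both 0s and 1s for isosurfacing")
    padded = np.pad(data.astype(float), 1)
    for field_ in (padded, gaussian_filter(padded, 0.7)):
        verts, faces, _, _ = measure.marching_cubes(field_, level=level)
        # padded index -> voxel-center mm coordinates
        verts = (verts - 1 + 0.5) * m.spacing + m.origin
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if mesh.is_watertight:
            if mesh.volume < 0:
                mesh.invert()
            return mesh
    raise GeometryError("isosurface extraction produced an open mesh")
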