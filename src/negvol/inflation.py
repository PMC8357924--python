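"""Constrained mesh inflation and negative-volume extraction.

The central operation of the pipeline: the reconstructed condyle mesh is
inflated outward along its vertex normals, one small step per iteration,
under Laplacian regularization (each free vertex is pulled toward the mean
of its neighbors so the advancing front stays smooth).  A vertex whose next
position would come within ``collision_tolerance`` of the bounding bone's
surface is projected to the contact point and frozen.  When every vertex is
frozen (or ``max_iters`` is reached) the inflated surface fills the joint
space; subtracting the original condyle solid and clipping below the neck
plane leaves the *negative volume* -- the empty space of the joint as a
watertight mesh.

Collision queries use a signed-distance grid sampled from the bounding mesh
(positive inside the bone solid), trilinearly interpolated; inside/outside
is decided by voxel-center ray parity, so the bound may be any watertight
mesh.  Boolean subtraction is voxel-based (rasterize both solids on a common
fine grid, subtract, re-extract the isosurface), which is robust for the
noisy marching-cubes meshes this pipeline produces.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage, sparse

from .errors import ConfigError, GeometryError
from .io_formats import Mask, TriMesh, Volume, mask_to_mesh, voxelize_mesh

logger = logging.getLogger("negvol")


@dataclass
class InflationParams:
    step: float = 0.1  # mm per iteration
    max_iters: int = 500
    laplacian_weight: float = 0.2  # lambda in [0, 1)
    collision_tolerance: float = 0.05  # mm
    sdf_spacing: float | None = None  # defaults to max(step, 2*collision_tolerance)
    clip_plane: tuple | None = None  # (point, normal) in mm
    #: deepest tolerated overlap of the *initial* mesh with the bound before
    #: it is treated as a geometry error rather than surface-contact noise;
    #: defaults to two SDF voxels
    max_initial_penetration: float | None = None

    def __post_init__(self):
        if self.step <= 0:
            raise ConfigError("step must be > 0")
        if self.max_iters < 1:
            raise ConfigError("max_iters must be >= 1")
        if not 0 <= self.laplacian_weight < 1:
            raise ConfigError(
                "laplacian_weight must be in [0, 1); weight 1 collapses every "
                "vertex onto its neighbor mean"
            )
        if self.collision_tolerance < 0:
            raise ConfigError("collision_tolerance must be >= 0")


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------

def vertex_normals(m: TriMesh, auto_reorient: bool = False) -> np.ndarray:
    """Unit vertex normals as the area-weighted average of incident face
    normals.  The mesh must be watertight and outward-oriented (signed
    volume > 0); with ``auto_reorient`` an inward mesh is flipped instead of
    raising."""
    if not m.is_watertight:
        raise GeometryError("vertex normals require a watertight mesh")
    if m.volume < 0:
        if not auto_reorient:
            raise GeometryError(
                "mesh is oriented inward (negative signed volume); "
                "pass auto_reorient=True to flip"
            )
        m = m.copy()
        m.invert()
    return _vertex_normals_raw(np.asarray(m.vertices), np.asarray(m.faces))


def _vertex_normals_raw(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = verts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area*normal
    areas = np.linalg.norm(fn, axis=1)
    if np.any(areas < 1e-14):
        raise GeometryError(f"{int((areas < 1e-14).sum())} degenerate faces")
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms < 1e-14] = 1.0
    return vn / norms[:, None]


# ---------------------------------------------------------------------------
# signed distance to a watertight solid
# ---------------------------------------------------------------------------

class SignedDistanceGrid:
    """Trilinearly interpolated signed distance to a solid's surface,
    positive inside, sampled on a regular grid (Euclidean distance
    transforms of the parity-rasterized solid)."""

    def __init__(self, sdf: np.ndarray, spacing: float, origin: np.ndarray):
        self.sdf = sdf
        self.spacing = float(spacing)
        self.origin = np.asarray(origin, dtype=float)

    @classmethod
    def from_mesh(cls, bound: TriMesh, spacing: float, padding: float = 3.0):
        lo = bound.bounds[0] - padding
        hi = bound.bounds[1] + padding
        shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 4)
        grid = Volume(np.zeros(tuple(shape)), np.full(3, spacing), lo)
        inside = voxelize_mesh(bound, grid, subdivide=False).data.astype(bool)
        s3 = (spacing,) * 3
        d_in = ndimage.distance_transform_edt(inside, sampling=s3)
        d_out = ndimage.distance_transform_edt(~inside, sampling=s3)
        return cls(d_in - d_out, spacing, lo)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Signed distance at mm points; points beyond the grid are treated
        as far outside the solid."""
        u = (np.asarray(points, dtype=float) - self.origin) / self.spacing - 0.5
        shape = np.array(self.sdf.shape)
        inside_grid = np.all((u >= 0) & (u <= shape - 1), axis=1)
        out = np.full(len(u), -1e6)
        if inside_grid.any():
            ui = u[inside_grid]
            i0 = np.floor(ui).astype(int)
            i0 = np.minimum(i0, shape - 2)
            f = ui - i0
            vals = np.zeros(len(ui))
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (
                            (f[:, 0] if dx else 1 - f[:, 0])
                            * (f[:, 1] if dy else 1 - f[:, 1])
                            * (f[:, 2] if dz else 1 - f[:, 2])
                        )
                        vals += w * self.sdf[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
            out[inside_grid] = vals
        return out


# ---------------------------------------------------------------------------
# inflation
# ---------------------------------------------------------------------------

def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def inflate(
    mc: TriMesh,
    bound: TriMesh | SignedDistanceGrid | None,
    p: InflationParams,
    frozen: np.ndarray | None = None,
    return_trace: bool = False,
):
    """Inflate ``mc`` along vertex normals until it fills the space bounded
    by ``bound``.

    Per iteration every free vertex moves by ``step`` along its (current)
    area-weighted normal, the free vertices are Laplacian-smoothed
    (``v <- (1-lambda) v + lambda mean(neighbors)``), and any vertex whose
    new position would come within ``collision_tolerance`` of the bound
    surface is bisected back to the contact point and frozen there.
    Terminates when all vertices are frozen or after ``max_iters``.

    ``bound=None`` inflates freely (useful for calibration).  ``frozen``
    optionally pins vertices from the start (e.g. below the neck plane).
    With ``return_trace`` a per-iteration record (enclosed volume, frozen
    fraction) is returned alongside the mesh.
    """
    if not mc.is_watertight:
        raise GeometryError("inflation requires a watertight starting mesh")
    if isinstance(bound, trimesh.Trimesh):
        if not bound.is_watertight:
            raise GeometryError("bounding mesh must be watertight")
        spacing = p.sdf_spacing or max(p.step, 2 * p.collision_tolerance)
        bound = SignedDistanceGrid.from_mesh(bound, spacing)

    verts = np.asarray(mc.vertices, dtype=float).copy()
    faces = np.asarray(mc.faces).copy()
    if _signed_volume(verts, faces) < 0:
        faces = faces[:, ::-1]

    n_v = len(verts)
    free = np.ones(n_v, dtype=bool)
    if frozen is not None:
        free &= ~np.asarray(frozen, dtype=bool)

    # neighbor averaging operator (combinatorial Laplacian smoothing)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    adj = sparse.coo_matrix(
        (np.ones(len(edges) * 2), (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n_v, n_v),
    ).tocsr()
    adj.data[:] = 1.0
    adj.sum_duplicates()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0

    tol = p.collision_tolerance
    if bound is not None:
        d0 = bound(verts)
        # deep overlap of the two solids is a genuine geometry error;
        # shallower contact (mask adjacency, interpolation noise) just
        # freezes those vertices where they are
        allowed = p.max_initial_penetration
        if allowed is None:
            allowed = max(tol, 2 * bound.spacing)
        if np.any(d0 > allowed):
            raise GeometryError(
                "starting mesh penetrates the bounding solid "
                f"(max signed distance {d0.max():.3f} mm)"
            )
        newly = free & (d0 >= -tol)
        free &= ~newly

    trace = []
    for it in range(p.max_iters):
        if not free.any():
            break
        normals = _vertex_normals_raw(verts, faces)
        prop = verts.copy()
        prop[free] += p.step * normals[free]
        lam = p.laplacian_weight
        if lam > 0:
            neigh = (adj @ prop) / deg[:, None]
            prop[free] = (1 - lam) * prop[free] + lam * neigh[free]
        if bound is not None:
            d = bound(prop)
            hit = free & (d >= -tol)
            if hit.any():
                lo = verts[hit].copy()
                hi = prop[hit].copy()
                for _ in range(20):  # bisect to the tolerance shell
                    mid = 0.5 * (lo + hi)
                    inside = bound(mid) >= -tol
                    hi[inside] = mid[inside]
                    lo[~inside] = mid[~inside]
                prop[hit] = lo
                free &= ~hit
        verts = prop
        if return_trace:
            trace.append(
                {
                    "iteration": it,
                    "volume_mm3": _signed_volume(verts, faces),
                    "frozen_fraction": 1.0 - free.mean(),
                }
            )
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if return_trace:
        return out, trace
    return out


# ---------------------------------------------------------------------------
# neck clipping
# ---------------------------------------------------------------------------

def clip_neck(m: TriMesh, point, normal) -> TriMesh:
    """Remove the half-space on the negative side of the plane and cap the
    cut with a planar polygon so the result stays watertight.

    The cap is fan-triangulated around each boundary loop's centroid, exact
    for the convex neck cross-sections this pipeline cuts.
    """
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    verts = np.asarray(m.vertices, dtype=float)
    faces = np.asarray(m.faces)
    s = (verts - point) @ normal
    # nudge the plane by a negligible offset so no vertex lies exactly on it
    # (exact incidences would create degenerate cut triangles)
    scale = float(np.linalg.norm(m.extents)) or 1.0
    delta = 1e-6 * scale
    while np.any(np.abs(s) < 1e-9 * scale):
        s = s + delta
    keep_v = s >= 0

    face_keep = keep_v[faces]
    n_keep = face_keep.sum(axis=1)
    if np.all(n_keep == 3):
        return m.copy()
    if not np.any(n_keep > 0):
        raise GeometryError("clip plane removes the entire mesh")

    new_verts = list(verts)
    new_faces = [f for f in faces[n_keep == 3]]
    cut_cache: dict[tuple[int, int], int] = {}

    def cut_point(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in cut_cache:
            t = s[i] / (s[i] - s[j])
            new_verts.append(verts[i] + t * (verts[j] - verts[i]))
            cut_cache[key] = len(new_verts) - 1
        return cut_cache[key]

    boundary_segments = []  # directed (a, b) along the kept surface winding
    for f in faces[(n_keep == 1) | (n_keep == 2)]:
        kept = [i for i in f if keep_v[i]]
        if len(kept) == 1:
            # rotate so f = (A kept, B cut, C cut)
            while not keep_v[f[0]]:
                f = np.roll(f, -1)
            a, b, c = f
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            new_faces.append([a, pab, pca])
            boundary_segments.append((pab, pca))
        else:
            # rotate so f = (A cut, B kept, C kept)
            while keep_v[f[0]]:
                f = np.roll(f, -1)
            a, b, c = f
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            new_faces.append([pab, b, c])
            new_faces.append([pab, c, pca])
            boundary_segments.append((pca, pab))

    # assemble boundary loops and cap each with a centroid fan
    succ = dict(boundary_segments)
    visited = set()
    for start in list(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = succ.get(start)
        while cur is not None and cur != start:
            loop.append(cur)
            visited.add(cur)
            cur = succ.get(cur)
        if cur != start or len(loop) < 3:
            raise GeometryError("clip produced an open boundary; cannot cap")
        centroid = np.mean([new_verts[i] for i in loop], axis=0)
        new_verts.append(centroid)
        ci = len(new_verts) - 1
        for a, b in zip(loop, loop[1:] + loop[:1]):
            new_faces.append([b, a, ci])

    out = trimesh.Trimesh(vertices=np.array(new_verts), faces=np.array(new_faces), process=True)
    if not out.is_watertight:
        raise GeometryError("clipped mesh is not watertight")
    if out.volume < 0:
        out.invert()
    return out


# ---------------------------------------------------------------------------
# boolean difference and measures
# ---------------------------------------------------------------------------

def _empty_mesh() -> TriMesh:
    return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))


def boolean_difference(
    a: TriMesh,
    b: TriMesh,
    voxel_size: float | None = None,
    max_voxels: int = 8_000_000,
    half_space: tuple | None = None,
) -> TriMesh:
    """Watertight solid difference ``a \\ b`` via a common voxel grid.

    Both solids are rasterized by the exact center-parity test, subtracted,
    optionally intersected with a half-space ``(point, normal)`` (voxel
    centers with negative side removed), and the result isosurfaced back to
    a mesh.  ``voxel_size`` defaults to 1/128 of the smallest extent of
    ``a`` (clamped by ``max_voxels``)."""
    for mesh, name in ((a, "a"), (b, "b")):
        if len(mesh.faces) and not mesh.is_watertight:
            raise GeometryError(f"operand {name} is not watertight")
    if len(a.faces) == 0:
        return _empty_mesh()
    lo, hi = a.bounds[0].copy(), a.bounds[1].copy()
    extent = hi - lo
    if voxel_size is None:
        voxel_size = float(extent.min()) / 128.0
    shape = np.ceil(extent / voxel_size).astype(int) + 4
    while np.prod(shape, dtype=np.int64) > max_voxels:
        voxel_size *= 1.26
        shape = np.ceil(extent / voxel_size).astype(int) + 4
    origin = lo - 2 * voxel_size
    grid = Volume(np.zeros(tuple(shape)), np.full(3, voxel_size), origin)
    va = voxelize_mesh(a, grid, subdivide=False).data.astype(bool)
    vb = (
        voxelize_mesh(b, grid, subdivide=False).data.astype(bool)
        if len(b.faces)
        else np.zeros_like(va)
    )
    diff = va & ~vb
    if half_space is not None:
        pt, nrm = (np.asarray(x, dtype=float) for x in half_space)
        xs, ys, zs = Volume(np.zeros(tuple(shape)), grid.spacing, origin).voxel_centers_1d()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        side = (X - pt[0]) * nrm[0] + (Y - pt[1]) * nrm[1] + (Z - pt[2]) * nrm[2]
        diff &= side >= 0
    # drop sub-voxel debris and voxels connected only across edges/corners --
    # they would make the extracted isosurface non-manifold
    diff = ndimage.binary_opening(diff, ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(diff)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        diff = np.isin(labels, np.flatnonzero(sizes >= max(27, 0.001 * sizes.max())) + 1)
    if not diff.any():
        return _empty_mesh()
    return mask_to_mesh(Mask(diff.astype(np.uint8), grid.spacing, origin))


def mesh_measures(m: TriMesh) -> tuple[float, float]:
    """(volume mm^3, surface area mm^2); volume by signed tetrahedron sum
    (requires a watertight mesh), area by triangle-area sum."""
    if len(m.faces) == 0:
        return 0.0, 0.0
    area = float(m.area)
    if not m.is_watertight:
        raise GeometryError("volume of an open mesh is undefined")
    return float(abs(m.volume)), area


# ---------------------------------------------------------------------------
# neck plane estimation and the combined negative-volume operation
# ---------------------------------------------------------------------------

def estimate_neck_clip_plane(m: TriMesh, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Default clip plane: perpendicular to the mesh's principal axis,
    placed at the neck's minimal cross-section (the thinnest vertex band
    along the axis, searched away from the condyle head)."""
    verts = np.asarray(m.vertices, dtype=float)
    c = verts.mean(axis=0)
    _, _, vt = np.linalg.svd(verts - c, full_matrices=False)
    axis = vt[0]
    t = (verts - c) @ axis
    rad = np.linalg.norm((verts - c) - np.outer(t, axis), axis=1)
    edges_t = np.linspace(t.min(), t.max(), bins + 1)
    centers, widths = [], []
    for i in range(bins):
        sel = (t >= edges_t[i]) & (t < edges_t[i + 1])
        if sel.sum() >= 3:
            centers.append(0.5 * (edges_t[i] + edges_t[i + 1]))
            widths.append(rad[sel].mean())
    centers, widths = np.array(centers), np.array(widths)
    # head = widest band; search the minimal cross-section on the far side
    head = centers[int(np.argmax(widths))]
    tail = centers[np.abs(centers - head) > 0.25 * (t.max() - t.min())]
    if len(tail) == 0:  # near-spherical mesh: clip through the centroid
        return c, axis if axis[2] >= 0 else -axis
    wtail = widths[np.abs(centers - head) > 0.25 * (t.max() - t.min())]
    neck_t = tail[int(np.argmin(wtail))]
    point = c + neck_t * axis
    normal = axis if head > neck_t else -axis  # keep the condyle side
    return point, normal


def fit_condyle_sphere(m: TriMesh) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit to the condyle head.

    Vertices within 1.6 head radii of the top along the principal axis are
    fitted algebraically (``|v|^2 = 2 v.c + (R^2 - |c|^2)``), with one
    reweighting pass that discards outliers (neck vertices).  Used to place
    the equatorial clip plane of a ball-and-socket joint."""
    verts = np.asarray(m.vertices, dtype=float)
    c0 = verts.mean(axis=0)
    _, _, vt = np.linalg.svd(verts - c0, full_matrices=False)
    axis = vt[0]
    t = (verts - c0) @ axis
    rho = np.linalg.norm((verts - c0) - np.outer(t, axis), axis=1)
    r_guess = rho.max()
    # orient the axis so +t points toward the head (the widest slice)
    if t[np.argmax(rho)] < t.mean():
        axis, t = -axis, -t
    sel = t > t.max() - 1.6 * r_guess
    for _ in range(2):
        v = verts[sel]
        A = np.c_[2 * v, np.ones(len(v))]
        b = (v**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        center = sol[:3]
        radius = float(np.sqrt(sol[3] + center @ center))
        resid = np.abs(np.linalg.norm(verts - center, axis=1) - radius)
        new_sel = sel & (resid < 2 * np.median(resid[sel]) + 1e-9)
        if new_sel.sum() < 10:
            break
        sel = new_sel
    return center, radius


def condyle_equator_from_mask(mask, toward_sign: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Equatorial clip plane of a ball-shaped bone from its voxel mask.

    For an axial stack the ball's per-slice cross-section area follows
    ``A(z) = pi (r^2 - (z - c_z)^2)``; the parabola vertex of the area
    profile around its maximum gives a sub-voxel equator height that is
    robust to the mesh being cut at the VOI walls.  The plane point is the
    max-area slice centroid; the normal is ``+-z`` (``toward_sign`` picks
    the side of the socket)."""
    data = mask.data.astype(bool)
    if not data.any():
        raise GeometryError("empty mask")
    areas = data.sum(axis=(0, 1)).astype(float)
    k0 = int(np.argmax(areas))
    ks = np.arange(max(0, k0 - 2), min(len(areas), k0 + 3))
    if len(ks) >= 3 and np.all(areas[ks] > 0):
        coef = np.polyfit(ks, areas[ks], 2)
        kz = float(-coef[1] / (2 * coef[0])) if coef[0] < 0 else float(k0)
        if not (ks[0] <= kz <= ks[-1]):
            kz = float(k0)
    else:
        kz = float(k0)
    xy = np.argwhere(data[:, :, k0]).mean(axis=0)
    point = mask.origin + (np.array([xy[0], xy[1], kz]) + 0.5) * mask.spacing
    normal = np.array([0.0, 0.0, np.sign(toward_sign) or 1.0])
    return point, normal


def negative_volume(
    mc_mesh: TriMesh,
    bound_mesh: TriMesh,
    params: InflationParams | None = None,
    clip_plane: tuple | None = None,
    voxel_size: float | None = None,
):
    """Full negative-volume extraction for one joint.

    Inflates the condyle mesh inside the socket bound, subtracts the
    original condyle, and clips below the neck plane; returns
    ``(mesh, volume_mm3, area_mm2, trace)``.  Vertices already below the
    clip plane are pinned -- they cannot contribute above it and letting
    them creep downward only degrades the front."""
    params = params or InflationParams()
    if clip_plane is None:
        clip_plane = params.clip_plane or estimate_neck_clip_plane(mc_mesh)
    pt, nrm = (np.asarray(x, dtype=float) for x in clip_plane)
    nrm = nrm / np.linalg.norm(nrm)
    below = (np.asarray(mc_mesh.vertices) - pt) @ nrm < -2 * params.step
    inflated, trace = inflate(mc_mesh, bound_mesh, params, frozen=below, return_trace=True)
    neg = boolean_difference(
        inflated, mc_mesh, voxel_size=voxel_size, half_space=(pt, nrm)
    )
    vol, area = mesh_measures(neg)
    return neg, vol, area, trace
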