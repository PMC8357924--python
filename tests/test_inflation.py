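import math

import numpy as np
import pytest
import trimesh

from negvol import (
    ConfigError,
    GeometryError,
    InflationParams,
    PhantomSpec,
    boolean_difference,
    clip_neck,
    condyle_equator_from_mask,
    fit_condyle_sphere,
    inflate,
    make_joint_phantom,
    mesh_measures,
    negative_volume,
    vertex_normals,
)


@pytest.fixture(scope="module")
def shell_bound():
    """Solid spherical shell with inner radius 8 (outer 10)."""
    outer = trimesh.creation.icosphere(4, radius=10.0)
    inner = trimesh.creation.icosphere(4, radius=8.0)
    return boolean_difference(outer, inner, voxel_size=0.15)


# ------------------------------------------------------------------ normals

def test_sphere_normals_are_radial():
    s = trimesh.creation.icosphere(3, radius=1.0)
    n = vertex_normals(s)
    radial = s.vertices / np.linalg.norm(s.vertices, axis=1, keepdims=True)
    angles = np.degrees(np.arccos(np.clip(np.sum(n * radial, axis=1), -1, 1)))
    assert angles.max() < 2.0


def test_cube_face_normals_axis_aligned():
    cube = trimesh.creation.box(extents=[2, 2, 2])
    sub = cube.subdivide()
    n = vertex_normals(sub)
    # face-interior vertices (exactly one zero-distance-to-face coordinate)
    verts = np.asarray(sub.vertices)
    interior = np.sum(np.isclose(np.abs(verts), 1.0), axis=1) == 1
    axis_aligned = np.isclose(np.abs(n[interior]).max(axis=1), 1.0, atol=1e-6)
    assert axis_aligned.all()


def test_inverted_mesh_rejected_unless_reoriented():
    s = trimesh.creation.icosphere(2, radius=1.0)
    flipped = trimesh.Trimesh(s.vertices, s.faces[:, ::-1], process=False)
    with pytest.raises(GeometryError):
        vertex_normals(flipped)
    n = vertex_normals(flipped, auto_reorient=True)
    radial = s.vertices / np.linalg.norm(s.vertices, axis=1, keepdims=True)
    assert np.sum(n * radial) > 0


# ----------------------------------------------------------------- inflate

def test_inflation_contact_with_spherical_shell(shell_bound):
    """Sphere r=5 inside an inner-radius-8 shell: all final vertex radii lie
    within step+tolerance of 8."""
    mc = trimesh.creation.icosphere(3, radius=5.0)
    p = InflationParams(step=0.1, max_iters=100, laplacian_weight=0.0,
                        collision_tolerance=0.05)
    out = inflate(mc, shell_bound, p)
    radii = np.linalg.norm(out.vertices, axis=1)
    assert radii.min() >= 8 - (p.step + p.collision_tolerance)
    assert radii.max() <= 8 + (p.step + p.collision_tolerance)


def test_free_inflation_radial_displacement():
    mc = trimesh.creation.icosphere(3, radius=5.0)
    out = inflate(mc, None, InflationParams(step=0.1, max_iters=10, laplacian_weight=0.0))
    radii = np.linalg.norm(out.vertices, axis=1)
    assert np.allclose(radii, 6.0, atol=1e-6)


def test_inflation_volume_nondecreasing(shell_bound):
    mc = trimesh.creation.icosphere(3, radius=5.0)
    p = InflationParams(step=0.1, max_iters=60, laplacian_weight=0.2)
    _, trace = inflate(mc, shell_bound, p, return_trace=True)
    vols = [t["volume_mm3"] for t in trace]
    assert all(b >= a - 1e-9 for a, b in zip(vols, vols[1:]))


def test_inflation_respects_collision_tolerance(shell_bound):
    mc = trimesh.creation.icosphere(3, radius=5.0)
    p = InflationParams(step=0.1, max_iters=100, laplacian_weight=0.2,
                        collision_tolerance=0.05)
    out = inflate(mc, shell_bound, p)
    radii = np.linalg.norm(out.vertices, axis=1)
    assert (radii <= 8 + p.collision_tolerance + p.step).all()


def test_pathological_laplacian_weight_rejected():
    with pytest.raises(ConfigError):
        InflationParams(laplacian_weight=1.0)


def test_inflate_requires_watertight():
    s = trimesh.creation.icosphere(2, radius=1.0)
    open_mesh = trimesh.Trimesh(s.vertices, s.faces[:-3], process=False)
    with pytest.raises(GeometryError):
        inflate(open_mesh, None, InflationParams(max_iters=1))


# --------------------------------------------------------------- clip_neck

def test_clip_sphere_hemisphere_volume():
    s = trimesh.creation.icosphere(4, radius=1.0)
    h = clip_neck(s, [0, 0, 0], [0, 0, 1])
    assert h.is_watertight
    assert h.volume == pytest.approx(2 / 3 * math.pi, rel=0.02)


def test_clip_plane_below_mesh_is_identity():
    s = trimesh.creation.icosphere(3, radius=1.0)
    out = clip_neck(s, [0, 0, -5], [0, 0, 1])
    assert len(out.faces) == len(s.faces)


def test_clip_random_planes_watertight():
    s = trimesh.creation.icosphere(3, radius=1.0)
    rng = np.random.default_rng(0)
    for _ in range(8):
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        out = clip_neck(s, rng.uniform(-0.4, 0.4, 3), n)
        assert out.is_watertight and out.volume > 0


def test_clip_removing_everything_raises():
    s = trimesh.creation.icosphere(2, radius=1.0)
    with pytest.raises(GeometryError):
        clip_neck(s, [0, 0, 5], [0, 0, 1])


# ------------------------------------------------------ boolean difference

def test_boolean_difference_nested_spheres():
    a = trimesh.creation.icosphere(4, radius=2.0)
    b = trimesh.creation.icosphere(4, radius=1.0)
    vol, _ = mesh_measures(boolean_difference(a, b))
    assert vol == pytest.approx(4 / 3 * math.pi * (8 - 1), rel=0.02)


def test_boolean_difference_self_and_disjoint():
    a = trimesh.creation.icosphere(3, radius=2.0)
    assert mesh_measures(boolean_difference(a, a)) == (0.0, 0.0)
    far = trimesh.creation.icosphere(3, radius=0.5)
    far.apply_translation([10, 0, 0])
    vol, _ = mesh_measures(boolean_difference(a, far))
    assert vol == pytest.approx(a.volume, rel=0.02)


def test_boolean_difference_volume_identity():
    """vol(a \\ b) = vol(a) - vol(a intersect b) on analytic solids."""
    a = trimesh.creation.icosphere(4, radius=2.0)
    b = trimesh.creation.icosphere(4, radius=1.5)
    b.apply_translation([1.5, 0, 0])
    diff_vol, _ = mesh_measures(boolean_difference(a, b, voxel_size=0.02))
    # independent oracle: voxel count of the analytic intersection
    h = 0.02
    n = int(5.0 / h)
    xs = -2.5 + (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    in_a = X**2 + Y**2 + Z**2 < 4
    in_b = (X - 1.5) ** 2 + Y**2 + Z**2 < 1.5**2
    inter_vol = np.sum(in_a & in_b) * h**3
    assert diff_vol == pytest.approx(a.volume - inter_vol, rel=0.01)


def test_nonwatertight_operand_rejected():
    a = trimesh.creation.icosphere(3, radius=1.0)
    broken = trimesh.Trimesh(a.vertices, a.faces[:-3], process=False)
    with pytest.raises(GeometryError):
        boolean_difference(broken, a)


# ------------------------------------------------------------ mesh_measures

def test_cube_measures_exact():
    assert mesh_measures(trimesh.creation.box(extents=[2, 2, 2])) == (8.0, 24.0)


def test_sphere_measures_within_1_percent():
    s = trimesh.creation.icosphere(5, radius=1.0)
    vol, area = mesh_measures(s)
    assert vol == pytest.approx(4 / 3 * math.pi, rel=0.01)
    assert area == pytest.approx(4 * math.pi, rel=0.01)


def test_mirror_invariance_of_measures():
    s = trimesh.creation.icosphere(3, radius=1.3)
    mirrored = trimesh.Trimesh(s.vertices * [-1, 1, 1], s.faces[:, ::-1], process=False)
    assert mesh_measures(mirrored)[0] == pytest.approx(mesh_measures(s)[0])
    assert mesh_measures(mirrored)[1] == pytest.approx(mesh_measures(s)[1])


def test_open_mesh_volume_rejected():
    s = trimesh.creation.icosphere(2, radius=1.0)
    open_mesh = trimesh.Trimesh(s.vertices, s.faces[:-3], process=False)
    with pytest.raises(GeometryError):
        mesh_measures(open_mesh)


# ------------------------------------------------- condyle fit + end-to-end

def test_fit_condyle_sphere_on_phantom():
    s = make_joint_phantom(PhantomSpec(), "left")
    center, radius = fit_condyle_sphere(s.mc_mesh)
    assert np.linalg.norm(center - s.condyle_center) < 0.2
    assert radius == pytest.approx(s.spec.condyle_radius, abs=0.2)


def test_condyle_equator_from_mask_on_phantom():
    s = make_joint_phantom(PhantomSpec(), "left")
    point, normal = condyle_equator_from_mask(s.mc_mask, toward_sign=1.0)
    assert abs(point[2] - s.condyle_center[2]) < 0.5
    assert np.allclose(normal, [0, 0, 1])


def test_negative_volume_recovers_analytic_shell():
    """inflate -> clip -> difference on the phantom recovers the
    closed-form shell volume within 10%."""
    s = make_joint_phantom(PhantomSpec(), "left")
    params = InflationParams(step=0.1, max_iters=60, laplacian_weight=0.2,
                             collision_tolerance=0.05)
    _, vol, area, trace = negative_volume(
        s.mc_mesh, s.tb_mesh, params, clip_plane=s.clip_plane
    )
    assert vol == pytest.approx(s.analytic_negative_volume, rel=0.10)
    assert trace[-1]["frozen_fraction"] > 0.5
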