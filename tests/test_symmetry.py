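import dataclasses
import json

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from negvol import (
    InflationParams,
    PhantomSpec,
    SymmetryConfig,
    hausdorff,
    make_joint_phantom,
    mirror_align,
    negative_volume,
    sample_cloud,
    surface_ratio,
    symmetry_report,
)


def _brute_force_hausdorff(l, r):
    d = np.linalg.norm(l[:, None, :] - r[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


# ---------------------------------------------------------------- hausdorff

def test_hausdorff_identity_and_single_pair():
    cloud = np.random.default_rng(0).normal(size=(50, 3))
    assert hausdorff(cloud, cloud) == 0.0
    assert hausdorff(np.array([[0.0, 0, 0]]), np.array([[3.0, 0, 0]])) == 3.0


@pytest.mark.parametrize("seed", range(5))
def test_hausdorff_matches_brute_force_200_points(seed):
    rng = np.random.default_rng(seed)
    l = rng.normal(size=(200, 3))
    r = rng.normal(size=(200, 3)) + 0.3
    assert hausdorff(l, r) == _brute_force_hausdorff(l, r)


@given(st.integers(0, 2**31 - 1))
def test_hausdorff_metric_axioms(seed):
    rng = np.random.default_rng(seed)
    a, b, c = (rng.normal(size=(20, 3)) for _ in range(3))
    hab, hba = hausdorff(a, b), hausdorff(b, a)
    assert hab == hba  # symmetry
    assert hab >= 0
    assert hausdorff(a, c) <= hab + hausdorff(b, c) + 1e-9  # triangle


def test_hausdorff_rigid_invariance():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(40, 3))
    b = rng.normal(size=(40, 3))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    t = np.array([1.0, -2.0, 0.5])
    assert hausdorff(a @ R.T + t, b @ R.T + t) == pytest.approx(hausdorff(a, b), abs=1e-9)


def test_hausdorff_empty_cloud_rejected():
    with pytest.raises(ValueError):
        hausdorff(np.zeros((0, 3)), np.zeros((2, 3)))


# ------------------------------------------------------------ surface ratio

def test_surface_ratio_closed_forms():
    assert surface_ratio(5.0, 5.0) == 1.0
    # spheres of radius r and 2r: areas scale with r^2 -> ratio 4
    r = 1.7
    assert surface_ratio(4 * np.pi * r**2, 4 * np.pi * (2 * r) ** 2) == pytest.approx(4.0)
    assert surface_ratio(3.0, 7.0) == surface_ratio(7.0, 3.0)


@given(st.floats(0.1, 1e3), st.floats(0.1, 1e3))
def test_surface_ratio_at_least_one(a, b):
    assert surface_ratio(a, b) >= 1.0


def test_surface_ratio_scale_covariance():
    """Scaling one mesh by s multiplies S_LR by s^2 (when it is the max)."""
    s = 1.5
    base = 10.0
    assert surface_ratio(base, base * s**2) == pytest.approx(s**2)


def test_surface_ratio_rejects_nonpositive():
    with pytest.raises(ValueError):
        surface_ratio(0.0, 1.0)


# -------------------------------------------------------------- mirror_align

def test_mirror_is_involution():
    mesh = trimesh.creation.icosphere(2, radius=1.0)
    mesh.apply_translation([3, 1, 0])
    plane = ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    once, _ = mirror_align(mesh, plane)
    twice, _ = mirror_align(once, plane)
    assert np.allclose(twice.vertices, mesh.vertices, atol=1e-12)
    assert once.volume == pytest.approx(mesh.volume)  # orientation preserved


# ------------------------------------------------------------ full reports

@pytest.fixture(scope="module")
def phantom_negatives():
    """Left negative volumes of a symmetric and an asymmetric phantom."""
    params = InflationParams(step=0.1, max_iters=60, laplacian_weight=0.2)
    out = {}
    for name, af in (("sym", 1.0), ("asym", 1.2)):
        spec = PhantomSpec(asymmetry_factor=af)
        meshes = {}
        for side in ("left", "right"):
            s = make_joint_phantom(spec, side)
            neg, _, _, _ = negative_volume(s.mc_mesh, s.tb_mesh, params,
                                           clip_plane=s.clip_plane)
            meshes[side] = neg
        out[name] = meshes
    return out


def test_identical_mirrored_meshes_perfectly_symmetric():
    mesh = trimesh.creation.icosphere(3, radius=2.0)
    mesh.apply_translation([-4, 0, 0])
    mirrored, _ = mirror_align(mesh, ((0, 0, 0), (1, 0, 0)))
    report = symmetry_report(mesh, mirrored, SymmetryConfig())
    assert report.S_LR == pytest.approx(1.0)
    assert report.H_LR == pytest.approx(0.0, abs=1e-9)


def test_symmetric_phantom_pair_low_metrics(phantom_negatives):
    sym = phantom_negatives["sym"]
    # the two joints are built in the same local frame: mirror about their
    # common lateral center plane
    mid = sym["left"].vertices[:, 0].mean()
    cfg = SymmetryConfig(mid_plane=((mid, 0, 0), (1, 0, 0)))
    report = symmetry_report(sym["left"], sym["right"], cfg)
    edge = float(np.mean(sym["left"].edges_unique_length))
    assert report.H_LR < 2 * max(edge, 0.75)
    assert report.S_LR < 1.02


def test_asymmetric_phantom_pair_larger_metrics(phantom_negatives):
    mid_s = phantom_negatives["sym"]["left"].vertices[:, 0].mean()
    mid_a = phantom_negatives["asym"]["left"].vertices[:, 0].mean()
    rep_s = symmetry_report(
        phantom_negatives["sym"]["left"], phantom_negatives["sym"]["right"],
        SymmetryConfig(mid_plane=((mid_s, 0, 0), (1, 0, 0))))
    rep_a = symmetry_report(
        phantom_negatives["asym"]["left"], phantom_negatives["asym"]["right"],
        SymmetryConfig(mid_plane=((mid_a, 0, 0), (1, 0, 0))))
    assert rep_a.S_LR > rep_s.S_LR
    assert rep_a.H_LR > rep_s.H_LR
    # analytic S_LR of the gap-x1.2 pair
    spec = PhantomSpec(asymmetry_factor=1.2)
    expected = spec.analytic_negative_area("right") / spec.analytic_negative_area("left")
    assert rep_a.S_LR == pytest.approx(expected, rel=0.10)


def test_report_flagging_threshold(phantom_negatives):
    mid = phantom_negatives["asym"]["left"].vertices[:, 0].mean()
    cfg = SymmetryConfig(mid_plane=((mid, 0, 0), (1, 0, 0)), flag_threshold=1.042)
    rep = symmetry_report(phantom_negatives["asym"]["left"],
                          phantom_negatives["asym"]["right"], cfg)
    assert rep.asymmetric


def test_report_json_serializable(phantom_negatives):
    sym = phantom_negatives["sym"]
    mid = sym["left"].vertices[:, 0].mean()
    rep = symmetry_report(sym["left"], sym["right"],
                          SymmetryConfig(mid_plane=((mid, 0, 0), (1, 0, 0))))
    parsed = json.loads(rep.to_json())
    for key in ("H_LR_mm", "H_LR_mean_mm", "H_LR_sd_mm", "S_LR",
                "S_L_mm2", "S_R_mm2", "V_L_mm3", "V_R_mm3", "alignment"):
        assert key in parsed
    assert rep.to_csv_row().count("\n") == 2


def test_surface_sampling_cloud_mode():
    mesh = trimesh.creation.icosphere(3, radius=1.0)
    cloud = sample_cloud(mesh, mode="surface", n=500, seed=1)
    assert cloud.shape == (500, 3)
    assert np.allclose(np.linalg.norm(cloud, axis=1), 1.0, atol=0.05)
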