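"""Rigid ICP + thin-plate-spline registration and common-volume cropping."""

import numpy as np
import pytest

from dermatrace import synthetic
from dermatrace.core import GeometryError, ImageStack, derive_seed
from dermatrace.registration import (CompositeTransform, DegenerateGeometryWarning,
                                     PointCloud, RigidTransform, crop_common_volume,
                                     extract_point_cloud, icp_rigid,
                                     register_point_clouds, tps_fit)


@pytest.fixture
def cloud():
    rng = np.random.default_rng(0)
    return PointCloud(rng.uniform(0, 100, size=(2500, 3)))


# ------------------------------------------------------------ point clouds

def test_empty_stack_gives_flagged_empty_cloud():
    st = ImageStack(np.zeros((4, 16, 16), np.uint8))
    pc = extract_point_cloud(st, threshold=10)
    assert pc.empty_flag and len(pc) == 0


def test_single_voxel_coordinate_convention():
    data = np.zeros((8, 16, 16), np.uint8)
    data[3, 5, 7] = 200
    pc = extract_point_cloud(ImageStack(data), threshold=100)
    np.testing.assert_allclose(pc.points[0], [7 * 0.427, 5 * 0.427, 3 * 1.0])


def test_cloud_lies_within_dilated_ground_truth_tubes(tube_render):
    """Point-in-dilated-tube oracle on a noiseless render."""
    import scipy.ndimage as ndi
    raw = tube_render["stack"]
    s8 = raw.with_data((raw.data // 257).astype(np.uint8))
    bg = int(np.median(s8.data))
    half_peak = bg + 0.5 * (int(s8.data.max()) - bg)
    pc = extract_point_cloud(s8, threshold=half_peak, max_points=5000, seed=0)
    assert len(pc) > 0
    gt = tube_render["labels"] == 1
    dilated = ndi.binary_dilation(gt, iterations=1)
    dx, dy, dz = tube_render["stack"].voxel_size
    idx = np.round(pc.points / [dx, dy, dz]).astype(int)[:, ::-1]
    assert dilated[idx[:, 0], idx[:, 1], idx[:, 2]].all()


# -------------------------------------------------------------------- ICP

def test_icp_identity_on_equal_clouds(cloud):
    res = icp_rigid(cloud, cloud)
    assert res.residual == pytest.approx(0.0, abs=1e-4)
    assert res.transform.angle_deg == pytest.approx(0.0, abs=1e-5)


def test_icp_recovers_known_rigid_motion(cloud):
    """5° rotation / 10 µm translation recovered to 0.1° / 0.1 µm."""
    T = RigidTransform.from_axis_angle([0.2, 0.5, 0.9], 5.0, [6.0, -5.0, 5.0])
    target = PointCloud(T.apply(cloud.points))
    res = icp_rigid(cloud, target)
    rot_err = RigidTransform(res.transform.rotation @ T.rotation.T,
                             np.zeros(3)).angle_deg
    assert rot_err <= 0.1
    assert np.linalg.norm(res.transform.translation - T.translation) <= 0.1


def test_icp_residual_history_non_increasing(cloud):
    rng = np.random.default_rng(3)
    moved = cloud.points + rng.normal(0, 0.8, cloud.points.shape)
    T = RigidTransform.from_axis_angle([1, 0, 0], 3.0, [4.0, 1.0, -2.0])
    res = icp_rigid(PointCloud(moved), PointCloud(T.apply(cloud.points)))
    hist = res.residual_history
    assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))


def test_icp_degenerate_collinear_cloud_warns_translation_only():
    line = np.outer(np.linspace(0, 50, 100), [1.0, 0.5, 0.0])
    with pytest.warns(DegenerateGeometryWarning):
        res = icp_rigid(PointCloud(line), PointCloud(line + [3.0, 1.0, 0.0]))
    np.testing.assert_allclose(res.transform.rotation, np.eye(3))


def test_icp_rigid_recovery_under_noise_and_missing_points():
    """1-voxel jitter + 20 % missing points: rotation < 1°, translation
    < 1 voxel, across many seeds."""
    rot_errs, trans_errs = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 80, size=(1500, 3))
        T = RigidTransform.from_axis_angle(rng.normal(size=3),
                                           rng.uniform(-4, 4),
                                           rng.uniform(-5, 5, 3))
        keep = rng.random(len(pts)) > 0.2
        jitter = rng.normal(0, 0.427, (keep.sum(), 3))
        src = PointCloud(pts[keep] + jitter)
        res = icp_rigid(src, PointCloud(T.apply(pts)))
        rot_errs.append(RigidTransform(res.transform.rotation @ T.rotation.T,
                                       np.zeros(3)).angle_deg)
        trans_errs.append(np.linalg.norm(res.transform.translation - T.translation))
    assert np.median(rot_errs) < 1.0
    assert np.median(trans_errs) < 1.0


def test_registration_symmetry_gives_mutually_inverse_transforms(cloud):
    T = RigidTransform.from_axis_angle([0, 1, 0.3], 4.0, [5.0, 2.0, -3.0])
    other = PointCloud(T.apply(cloud.points))
    ab = icp_rigid(cloud, other).transform
    ba = icp_rigid(other, cloud).transform
    comp = ab.compose(ba)
    assert comp.angle_deg <= 0.2
    assert np.linalg.norm(comp.translation) <= 0.2


def test_rigid_update_matches_simpleitk_landmark_fit(cloud):
    """Independent oracle: the closed-form rigid update agrees with
    SimpleITK's landmark-based rigid initializer on the same pairs."""
    sitk = pytest.importorskip("SimpleITK")
    T = RigidTransform.from_axis_angle([0.1, 0.9, 0.2], 7.0, [3.0, -1.0, 2.0])
    src = cloud.points[:200]
    dst = T.apply(src)
    from dermatrace.registration import _kabsch
    mine = _kabsch(src, dst)
    tx = sitk.LandmarkBasedTransformInitializer(
        sitk.VersorRigid3DTransform(),
        list(src.ravel()), list(dst.ravel()))
    probe = cloud.points[200:260]
    theirs = np.array([tx.TransformPoint(p) for p in probe])
    np.testing.assert_allclose(mine.apply(probe), theirs, atol=1e-3)


# -------------------------------------------------------------------- TPS

def test_tps_interpolates_at_zero_regularization():
    rng = np.random.default_rng(1)
    src = rng.uniform(0, 50, (30, 3))
    dst = src + rng.normal(0, 2, (30, 3))
    tps = tps_fit(src, dst, 0.0)
    assert np.abs(tps.apply(src) - dst).max() <= 1e-6


def test_tps_reproduces_affine_maps_exactly():
    rng = np.random.default_rng(2)
    src = rng.uniform(0, 50, (40, 3))
    A = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    b = rng.normal(size=3)
    tps = tps_fit(src, src @ A.T + b, 0.0)
    grid = rng.uniform(0, 50, (300, 3))
    assert np.abs(tps.apply(grid) - (grid @ A.T + b)).max() <= 1e-6


def test_tps_large_lambda_approaches_least_squares_affine():
    rng = np.random.default_rng(3)
    src = rng.uniform(0, 50, (40, 3))
    dst = src + rng.normal(0, 2, (40, 3))
    tps = tps_fit(src, dst, 1e6)
    P = np.hstack([np.ones((len(src), 1)), src])
    coef, *_ = np.linalg.lstsq(P, dst, rcond=None)
    grid = rng.uniform(0, 50, (200, 3))
    Pg = np.hstack([np.ones((len(grid), 1)), grid])
    assert np.abs(tps.apply(grid) - Pg @ coef).max() <= 1e-2


def test_tps_rejects_coplanar_landmarks():
    rng = np.random.default_rng(4)
    src = rng.uniform(0, 50, (20, 3))
    src[:, 2] = 7.0
    with pytest.raises(GeometryError):
        tps_fit(src, src + 1.0, 0.0)


# ------------------------------------------- composed recovery + cropping

def test_icp_tps_recovers_simulated_deformation(validation_config):
    """Registering a scene deformed by a known smooth rigid+non-rigid field
    recovers ground-truth node positions with median error < 2 µm."""
    cfg = validation_config
    scene = synthetic.make_baseline_scene(cfg, derive_seed(21, "forest"))
    moved = synthetic.apply_longitudinal_change(
        scene, synthetic.ChangeSpec(), derive_seed(21, "change"))
    base_skel = scene.skeleton
    sess_skel = synthetic.deformed_skeleton(moved, cfg)
    base_mask = synthetic.rasterize_fiber_mask(base_skel, cfg)
    sess_mask = synthetic.rasterize_fiber_mask(sess_skel, cfg)
    c_base = extract_point_cloud(ImageStack(base_mask.astype(np.uint8) * 255,
                                            cfg.voxel_size), threshold=127, seed=1)
    c_sess = extract_point_cloud(ImageStack(sess_mask.astype(np.uint8) * 255,
                                            cfg.voxel_size), threshold=127, seed=2)
    tf, _ = register_point_clouds(c_sess, c_base)
    mapped = tf.apply(sess_skel.nodes[["x", "y", "z"]].to_numpy())
    err = np.linalg.norm(
        mapped - moved.skeleton.nodes[["x", "y", "z"]].to_numpy(), axis=1)
    assert np.median(err) < 2.0


def test_crop_common_volume_box_arithmetic():
    rng = np.random.default_rng(5)
    stacks = [ImageStack(rng.integers(0, 255, (10, 32, 32)).astype(np.uint8),
                         voxel_size=(1.0, 1.0, 1.0)) for _ in range(2)]
    ident = CompositeTransform(RigidTransform.identity())
    out, (lo, hi) = crop_common_volume(stacks, [ident, ident])
    assert np.allclose(lo, 0)
    assert out[0].shape == out[1].shape
    # one session translated by d µm along x reduces the common x-extent by d
    d = 5.0
    shift = CompositeTransform(RigidTransform(np.eye(3), [-d, 0, 0]))
    out2, (lo2, hi2) = crop_common_volume(stacks, [ident, shift])
    assert (hi[0] - lo[0]) - (hi2[0] - lo2[0]) == pytest.approx(d, abs=1e-6)
    assert out2[0].shape == out2[1].shape


def test_crop_common_volume_requires_intersection():
    st = ImageStack(np.zeros((4, 8, 8), np.uint8), voxel_size=(1.0, 1.0, 1.0),
                    session="far")
    ident = CompositeTransform(RigidTransform.identity())
    away = CompositeTransform(RigidTransform(np.eye(3), [100.0, 0, 0]))
    with pytest.raises(GeometryError):
        crop_common_volume([st, st], [ident, away])
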