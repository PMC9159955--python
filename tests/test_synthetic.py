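"""Synthetic skin-innervation generator: geometry, rendering, tiling,
longitudinal change."""

import numpy as np
import pandas as pd
import pytest

from dermatrace import synthetic
from dermatrace.core import ConfigurationError, GeometryError, ImageStack, Skeleton
from dermatrace.synthetic import (ChangeSpec, NoiseParams, SimulationConfig,
                                  apply_longitudinal_change, deformed_skeleton,
                                  generate_fiber_forest, make_baseline_scene,
                                  make_quadrant_tiles, rasterize_fiber_mask,
                                  render_stack)


# ---------------------------------------------------------------- config

@pytest.mark.parametrize("bad", [
    dict(volume_dims=(0, 64, 32)),
    dict(voxel_size=(0.427, -1.0, 1.0)),
    dict(radius_thin=(0.3, 1.3), radius_thick=(1.2, 1.8)),   # ranges overlap
    dict(epidermal_band=(0.0, 500.0)),                       # outside z extent
    dict(n_trees_thin=-1),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**bad)


# ---------------------------------------------------------------- forests

def test_forest_deterministic_given_seed(tiny_config):
    a = generate_fiber_forest(tiny_config, seed=5)
    b = generate_fiber_forest(tiny_config, seed=5)
    pd.testing.assert_frame_equal(a.nodes, b.nodes)
    c = generate_fiber_forest(tiny_config, seed=6)
    assert not a.nodes.equals(c.nodes)


def test_zero_trees_gives_empty_forest():
    cfg = SimulationConfig(volume_dims=(64, 64, 32), n_trees_thin=0, n_trees_thick=0)
    skel = generate_fiber_forest(cfg, 0)
    assert skel.n_nodes == 0
    assert skel.total_length() == 0.0


def test_total_length_matches_bruteforce_segment_sum(tiny_config):
    """Oracle: explicit Euclidean sum over every parent→child polyline span."""
    skel = generate_fiber_forest(tiny_config, 3)
    pos = skel.nodes.set_index("id")[["x", "y", "z"]]
    total = 0.0
    for _, row in skel.nodes.iterrows():
        if row["parent"] < 0:
            continue
        p = pos.loc[row["parent"]].to_numpy(float)
        c = np.array([row["x"], row["y"], row["z"]], float)
        total += float(np.sqrt(((p - c) ** 2).sum()))
    assert skel.total_length() == pytest.approx(total, rel=1e-12)


def test_forest_geometry_contracts(tiny_config):
    skel = generate_fiber_forest(tiny_config, 4)
    ext = tiny_config.extent_um
    pts = skel.nodes[["x", "y", "z"]].to_numpy()
    assert (pts >= 0).all() and (pts <= np.array(ext)).all()
    assert (skel.nodes["radius"] > 0).all()
    # forest: every non-root has exactly one parent, no cycles
    parents = dict(zip(skel.nodes["id"], skel.nodes["parent"]))
    for i in skel.nodes["id"]:
        seen, cur = set(), i
        while parents.get(cur, -1) >= 0:
            assert cur not in seen
            seen.add(cur)
            cur = parents[cur]
    # epidermal flag is z above (shallower than) the boundary
    flags = skel.epidermal_flags()
    np.testing.assert_array_equal(
        flags, skel.nodes["z"].to_numpy() < tiny_config.epidermal_boundary_um)
    # thin trees reach the epidermis; thick trees end below the boundary
    cal = skel.caliber_of_tree()
    for t, c in cal.items():
        zmin = skel.nodes.loc[skel.nodes["tree_id"] == t, "z"].min()
        if c == "thick":
            assert zmin >= tiny_config.epidermal_boundary_um


# ---------------------------------------------------------------- rendering

def test_empty_scene_renders_uniform_background():
    cfg = SimulationConfig(volume_dims=(48, 48, 16), n_trees_thin=0,
                           n_trees_thick=0, af_intensity=0.0,
                           appendage_density=0.0,
                           noise=NoiseParams(poisson_scale=0.0, gauss_sigma=0.0))
    stack, labels = render_stack(Skeleton.empty(), cfg, 0)
    assert labels.max() == 0
    # only the depth ramp varies; each slice is constant
    for sl in stack.data:
        assert sl.min() == sl.max()


def test_centerline_brighter_than_far_background(tube_render):
    stack = tube_render["stack"].data
    labels = tube_render["labels"]
    zc, yc = int(30.0), int(round(20.0 / 0.427))
    on_line = stack[zc, yc, 30:240:25]
    far = stack[zc, yc + 30, 30:240:25]
    assert (on_line > far).all()


def test_depth_gain_ratio_matches_linear_ramp():
    """One tube duplicated shallow and deep: mean intensity ratio follows the
    configured surface→bottom excitation ramp within 5%."""
    from tests.conftest import straight_tube_skeleton
    sh = straight_tube_skeleton(z=8.0)
    dp = straight_tube_skeleton(z=40.0)
    dp.nodes["id"] += 1000
    dp.nodes.loc[dp.nodes["parent"] >= 0, "parent"] += 1000
    dp.nodes["tree_id"] = 1
    both = Skeleton(pd.concat([sh.nodes, dp.nodes], ignore_index=True), 15.0)
    cfg = SimulationConfig(volume_dims=(256, 96, 48), af_intensity=0.0,
                           appendage_density=0.0, background_intensity=0.0,
                           noise=NoiseParams(0.0, 0.0))
    stack, labels = render_stack(both, cfg, 0)
    mask_sh = rasterize_fiber_mask(sh, cfg)
    mask_dp = rasterize_fiber_mask(dp, cfg)
    nz = cfg.volume_dims[2]
    ramp = 1.0 + (cfg.depth_gain - 1.0) * np.arange(nz) / (nz - 1)
    expected = ramp[40] / ramp[8]
    measured = stack.data[mask_dp].mean() / stack.data[mask_sh].mean()
    assert measured == pytest.approx(expected, rel=0.05)


def test_rasterized_mask_matches_bruteforce_point_in_tube(tiny_config):
    """Conservation: voxel count equals an independent all-voxels ×
    all-segments point-in-tube test on a small volume."""
    skel = generate_fiber_forest(tiny_config, 9)
    mask = rasterize_fiber_mask(skel, tiny_config)
    nx, ny, nz = tiny_config.volume_dims
    dx, dy, dz = tiny_config.voxel_size
    pos = skel.nodes.set_index("id")
    child = skel.nodes[skel.nodes["parent"] >= 0]
    a = pos.loc[child["parent"], ["x", "y", "z"]].to_numpy(float)
    b = child[["x", "y", "z"]].to_numpy(float)
    ra = pos.loc[child["parent"], "radius"].to_numpy(float)
    rb = child["radius"].to_numpy(float)
    X, Y, Z = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy,
                          np.arange(nz) * dz, indexing="ij")
    P = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.zeros(len(P), dtype=bool)
    for p0, p1, r0, r1 in zip(a, b, ra, rb):
        v = p1 - p0
        vv = v @ v
        t = ((P - p0) @ v) / vv if vv > 0 else np.zeros(len(P))
        t = np.clip(t, 0.0, 1.0)
        closest = p0 + t[:, None] * v
        d2 = ((P - closest) ** 2).sum(axis=1)
        rloc = r0 + t * (r1 - r0)
        inside |= d2 <= rloc ** 2
    brute = inside.reshape(nx, ny, nz).transpose(2, 1, 0)
    assert mask.sum() == brute.sum()
    np.testing.assert_array_equal(mask, brute)


def test_render_rejects_out_of_volume_skeleton(tiny_config):
    skel = generate_fiber_forest(tiny_config, 1)
    skel.nodes.loc[0, "x"] = 1e4
    with pytest.raises(GeometryError):
        render_stack(skel, tiny_config, 0)


# ---------------------------------------------------------------- tiles

def test_quadrant_tiles_paper_geometry():
    """2,000-px stack with 100-px overlap yields four 1,050-px tiles."""
    stack = ImageStack(np.arange(2000 * 2000, dtype=np.uint16).reshape(1, 2000, 2000))
    tiles = make_quadrant_tiles(stack, 100)
    assert all(t.shape == (1, 1050, 1050) for t in tiles.tiles)
    assert tiles.true_offsets == [(0, 0), (950, 0), (0, 950), (950, 950)]


def test_quadrant_tiles_zero_overlap():
    stack = ImageStack(np.zeros((1, 2000, 2000), np.uint16))
    tiles = make_quadrant_tiles(stack, 0)
    assert all(t.shape == (1, 1000, 1000) for t in tiles.tiles)


def test_tiles_recompose_parent_exactly_and_cover_once_or_twice():
    rng = np.random.default_rng(0)
    stack = ImageStack(rng.integers(0, 65535, (3, 220, 220)).astype(np.uint16))
    tiles = make_quadrant_tiles(stack, 20)
    recomposed = np.zeros_like(stack.data)
    coverage = np.zeros(stack.shape[1:], dtype=int)
    for tile, (ox, oy) in zip(tiles.tiles, tiles.true_offsets):
        nz, h, w = tile.shape
        recomposed[:, oy:oy + h, ox:ox + w] = tile.data
        coverage[oy:oy + h, ox:ox + w] += 1
    np.testing.assert_array_equal(recomposed, stack.data)
    assert set(np.unique(coverage)) <= {1, 2, 4}
    # overlap strips are covered exactly twice (four-fold at the center cross)
    assert coverage[0, 0] == 1 and coverage[110, 0] == 2 and coverage[110, 110] == 4


def test_tiles_reject_inconsistent_dims():
    stack = ImageStack(np.zeros((1, 101, 101), np.uint16))
    with pytest.raises(GeometryError):
        make_quadrant_tiles(stack, 20)


# ------------------------------------------------- longitudinal change

def test_full_removal_empties_forest(tiny_config):
    scene = make_baseline_scene(tiny_config, 2)
    out = apply_longitudinal_change(scene, ChangeSpec(remove_frac_thin=1.0,
                                                      remove_frac_thick=1.0), 3)
    assert out.skeleton.n_nodes == 0
    assert set(out.change_record["removed"]) == set(scene.skeleton.tree_ids)


def test_regrowth_without_epidermal_entry_has_no_epidermal_nodes(tiny_config):
    scene = make_baseline_scene(tiny_config, 2)
    out = apply_longitudinal_change(
        scene, ChangeSpec(remove_frac_thin=1.0, remove_frac_thick=1.0,
                          regrow_frac_thin=1.0, epidermal_entry=False), 3)
    assert out.skeleton.n_nodes > 0
    assert not out.skeleton.epidermal_flags().any()


def test_regrown_fibers_retrace_baseline_within_jitter(tiny_config):
    """Nearest-neighbour oracle: every regrown node lies within the stated
    jitter distance of the original centerline."""
    from scipy.spatial import cKDTree
    scene = make_baseline_scene(tiny_config, 2)
    jitter = 0.5
    out = apply_longitudinal_change(
        scene, ChangeSpec(remove_frac_thin=1.0, regrow_frac_thin=1.0,
                          jitter_um=jitter), 3)
    regrown = out.change_record["regrown"]
    assert regrown
    base_pts = scene.skeleton.nodes[["x", "y", "z"]].to_numpy()
    tree = cKDTree(base_pts)
    new = out.skeleton.nodes[out.skeleton.nodes["tree_id"].isin(regrown)]
    d, _ = tree.query(new[["x", "y", "z"]].to_numpy())
    assert np.quantile(d, 0.99) < 4 * jitter


def test_change_fractions_validated():
    with pytest.raises(ConfigurationError):
        ChangeSpec(remove_frac_thin=1.5)


def test_deformation_is_smooth_and_invertible(tiny_config):
    """Numerical Jacobian of the displacement field stays below 1 in norm,
    so p ↦ p + u(p) cannot fold."""
    scene = make_baseline_scene(tiny_config, 2)
    out = apply_longitudinal_change(scene, ChangeSpec(), 3)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 25, size=(200, 3))
    eps = 1e-3
    for ax in range(3):
        d = np.zeros(3)
        d[ax] = eps
        g = (out.deformation.displacement(pts + d)
             - out.deformation.displacement(pts)) / eps
        assert np.abs(g).max() < 1.0


def test_deformed_skeleton_stays_in_volume(tiny_config):
    scene = make_baseline_scene(tiny_config, 2)
    out = apply_longitudinal_change(scene, ChangeSpec(rigid_trans_um=8.0), 3)
    skel = deformed_skeleton(out, tiny_config)
    ext = np.array(tiny_config.extent_um)
    pts = skel.nodes[["x", "y", "z"]].to_numpy()
    assert (pts >= 0).all() and (pts <= ext).all()


# ---------------------------------------------------------------- I/O

def test_swc_round_trip(tmp_path, tiny_config):
    skel = generate_fiber_forest(tiny_config, 8)
    path = tmp_path / "forest.swc"
    skel.save_swc(path)
    back = Skeleton.load_swc(path, tiny_config.epidermal_boundary_um)
    assert back.n_nodes == skel.n_nodes
    np.testing.assert_allclose(back.nodes[["x", "y", "z", "radius"]].to_numpy(),
                               skel.nodes[["x", "y", "z", "radius"]].to_numpy(),
                               atol=1e-4)
    assert list(back.nodes["caliber"]) == list(skel.nodes["caliber"])
    flags = pd.read_csv(path.with_suffix(".flags.csv"))
    np.testing.assert_array_equal(flags["epidermal"].to_numpy(dtype=bool),
                                  skel.epidermal_flags())


def test_stack_tiff_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    stack = ImageStack(rng.integers(0, 65535, (4, 32, 32)).astype(np.uint16),
                       session="s0", meta={"seed": 1})
    path = tmp_path / "stack.tif"
    stack.save(path)
    back = ImageStack.load(path)
    np.testing.assert_array_equal(back.data, stack.data)
    assert back.session == "s0"
    assert back.voxel_size == stack.voxel_size
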