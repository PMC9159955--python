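"""Structural-plasticity quantification: lengths, endings, epidermal
segmentation, longitudinal metrics and change maps."""

import networkx as nx
import numpy as np
import pytest

from dermatrace import synthetic
from dermatrace.core import derive_seed
from dermatrace.quantify import (BoundaryEstimationError, EpidermalSurface,
                                 count_endings, diff_fiber_graphs,
                                 estimate_epidermal_boundary,
                                 longitudinal_metrics, segment_epidermal_endings,
                                 total_fiber_length)
from dermatrace.tracing import skeleton_to_graph


def _graph_from_polyline(points, start_id=0):
    G = nx.Graph()
    pts = np.asarray(points, float)
    G.add_node(start_id, pos=pts[0], radius=0.3)
    G.add_node(start_id + 1, pos=pts[-1], radius=0.3)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    G.add_edge(start_id, start_id + 1, path=pts, length=length)
    G.graph["box_um"] = (0, 0, 0, 100, 100, 100)
    return G


# --------------------------------------------------------------- lengths

def test_total_length_empty_graph_is_zero():
    assert total_fiber_length(nx.Graph()) == 0.0


def test_total_length_pythagorean_polyline():
    """Vertices (0,0,0)-(3,4,0)-(3,4,12): 5 + 12 = 17 µm."""
    G = _graph_from_polyline([[0, 0, 0], [3, 4, 0], [3, 4, 12]])
    assert total_fiber_length(G) == pytest.approx(17.0)


def test_total_length_roi_clipping_exact():
    G = _graph_from_polyline([[0, 5, 5], [10, 5, 5]])
    roi = ((2.0, 0.0, 0.0), (6.0, 10.0, 10.0))
    assert total_fiber_length(G, roi) == pytest.approx(4.0)
    outside = ((50.0, 50.0, 50.0), (60.0, 60.0, 60.0))
    assert total_fiber_length(G, outside) == 0.0


def test_total_length_matches_bruteforce_on_simulated_scene(tiny_config):
    skel = synthetic.generate_fiber_forest(tiny_config, 13)
    G = skeleton_to_graph(skel)
    assert total_fiber_length(G) == pytest.approx(skel.total_length(), rel=1e-9)


# --------------------------------------------------------------- endings

def test_open_curve_has_two_endings():
    G = _graph_from_polyline([[20, 20, 20], [40, 20, 20]])
    n, pos = count_endings(G, boundary_margin_um=3.0)
    assert n == 2 and pos.shape == (2, 3)


def test_y_tree_has_three_endings():
    G = nx.Graph()
    pts = {0: [30, 30, 30], 1: [40, 30, 30], 2: [50, 40, 30], 3: [50, 20, 30]}
    for k, p in pts.items():
        G.add_node(k, pos=np.array(p, float))
    for a, b in [(0, 1), (1, 2), (1, 3)]:
        poly = np.array([pts[a], pts[b]], float)
        G.add_edge(a, b, path=poly, length=float(np.linalg.norm(poly[1] - poly[0])))
    G.graph["box_um"] = (0, 0, 0, 100, 100, 100)
    n, _ = count_endings(G, 3.0)
    assert n == 3


def test_border_touching_endpoint_not_counted():
    G = _graph_from_polyline([[0.5, 50, 50], [30, 50, 50]])
    n, _ = count_endings(G, boundary_margin_um=3.0)
    assert n == 1      # the face-touching endpoint is excluded


# ------------------------------------------------------- boundary surface

def test_flat_band_boundary_recovered(validation_config):
    """Simulator band ending at z = 15 µm → estimated surface 15 ± 2 µm."""
    scene = synthetic.make_baseline_scene(validation_config, derive_seed(7, "forest"))
    skel = synthetic.deformed_skeleton(scene, validation_config)
    _, labels = synthetic.render_stack(skel, validation_config,
                                       derive_seed(7, "render", "baseline"))
    surface = estimate_epidermal_boundary(labels, validation_config.voxel_size)
    expect = validation_config.epidermal_boundary_um
    assert abs(np.median(surface.zmap) - expect) <= 2.0
    assert np.quantile(np.abs(surface.zmap - expect), 0.9) <= 3.0


def test_tilted_band_slope_recovered():
    """Synthetic tilted band: recovered plane slope within 10 % of truth."""
    ny = nx_ = 96
    nz = 40
    labels = np.zeros((nz, ny, nx_), np.uint8)
    slope = 8.0 / nx_          # 8 µm drop across the field, dz = 1 µm
    for x in range(nx_):
        depth = int(round(10 + slope * x))
        labels[:depth, :, x] = 2
    surface = estimate_epidermal_boundary(labels, (1.0, 1.0, 1.0),
                                          psf_debias_um=0.0)
    fit = np.polyfit(np.arange(nx_), surface.zmap.mean(axis=0), 1)
    assert fit[0] == pytest.approx(slope, rel=0.10)


def test_boundary_requires_signal_or_metadata():
    with pytest.raises(BoundaryEstimationError):
        estimate_epidermal_boundary(np.zeros((4, 8, 8), np.uint8))
    surf = estimate_epidermal_boundary(None, metadata_depth_um=15.0,
                                       lateral_shape=(8, 8))
    assert (surf.zmap == 15.0).all()


# ------------------------------------------------- intra-epidermal endings

def test_graph_below_surface_has_no_epidermal_endings():
    G = _graph_from_polyline([[10, 10, 40], [30, 10, 40]])
    surf = EpidermalSurface(np.full((64, 64), 15.0), (1.0, 1.0))
    _, n = segment_epidermal_endings(G, surf)
    assert n == 0


def test_ground_truth_epidermal_ending_count_recovered(tiny_config):
    """From the ground-truth skeleton graph, the count equals the number of
    epidermal-flagged leaf nodes."""
    skel = synthetic.generate_fiber_forest(tiny_config, 3)
    G = skeleton_to_graph(skel)
    surf = estimate_epidermal_boundary(
        None, tiny_config.voxel_size,
        metadata_depth_um=tiny_config.epidermal_boundary_um,
        lateral_shape=(64, 64))
    sub, n = segment_epidermal_endings(G, surf)
    leaves = set(skel.nodes["id"]) - set(skel.nodes.loc[skel.nodes["parent"] >= 0,
                                                        "parent"])
    k = sum(1 for leaf in leaves
            if skel.nodes.set_index("id").loc[leaf, "z"]
            < tiny_config.epidermal_boundary_um)
    assert k > 0
    assert n == k


def test_suppressed_epidermal_entry_gives_zero_count(tiny_config):
    scene = synthetic.make_baseline_scene(tiny_config, 3)
    out = synthetic.apply_longitudinal_change(
        scene, synthetic.ChangeSpec(remove_frac_thin=1.0, regrow_frac_thin=1.0,
                                    epidermal_entry=False), 4)
    G = skeleton_to_graph(out.skeleton)
    surf = estimate_epidermal_boundary(
        None, tiny_config.voxel_size,
        metadata_depth_um=tiny_config.epidermal_boundary_um,
        lateral_shape=(64, 64))
    _, n = segment_epidermal_endings(G, surf)
    assert n == 0


# ------------------------------------------------------------ longitudinal

def test_baseline_versus_itself_is_100_percent(tiny_config):
    skel = synthetic.generate_fiber_forest(tiny_config, 3)
    G = skeleton_to_graph(skel)
    metrics = longitudinal_metrics([G, G], baseline_index=0)
    for key, v in metrics[1].percent_of_baseline.items():
        if v is not None:
            assert v == pytest.approx(100.0)


def test_zero_baseline_marks_percent_undefined():
    metrics = longitudinal_metrics([nx.Graph(), nx.Graph()], 0)
    assert metrics[1].percent_of_baseline["total_length"] is None


def test_regrowth_fraction_monotone_in_percent_of_baseline():
    """Percent-of-baseline total length increases strictly with the
    simulated regrowth fraction."""
    # four trees per caliber class so every quarter step regrows more trees
    cfg = synthetic.SimulationConfig(volume_dims=(96, 96, 32),
                                     epidermal_band=(0.0, 10.0),
                                     n_trees_thin=4, n_trees_thick=4)
    scene = synthetic.make_baseline_scene(cfg, 6)
    base = skeleton_to_graph(scene.skeleton)
    lengths = []
    for r in (0.0, 0.25, 0.5, 0.75, 1.0):
        out = synthetic.apply_longitudinal_change(
            scene, synthetic.ChangeSpec(remove_frac_thin=1.0,
                                        remove_frac_thick=1.0,
                                        regrow_frac_thin=r, regrow_frac_thick=r,
                                        deformation_amplitude_um=0.0,
                                        rigid_rot_deg=0.0, rigid_trans_um=0.0),
            seed=9)
        G = skeleton_to_graph(out.skeleton)
        m = longitudinal_metrics([base, G], 0)
        lengths.append(m[1].percent_of_baseline["total_length"])
    assert all(b > a for a, b in zip(lengths, lengths[1:]))
    assert lengths[0] == 0.0


# ------------------------------------------------------------- change maps

def test_identical_graphs_diff_all_stable(tiny_config):
    G = skeleton_to_graph(synthetic.generate_fiber_forest(tiny_config, 4))
    cm = diff_fiber_graphs(G, G, match_tol_um=3.0)
    assert not cm.lost and not cm.gained
    assert len(cm.stable_ref) == G.number_of_edges()
    assert len(cm.stable_new) == G.number_of_edges()


def test_removed_tree_reported_lost_exactly(tiny_config):
    skel = synthetic.generate_fiber_forest(tiny_config, 4)
    trees = list(skel.tree_ids)
    reduced = skel.subset_trees(trees[1:])
    G_ref = skeleton_to_graph(skel)
    G_new = skeleton_to_graph(reduced)
    cm = diff_fiber_graphs(G_ref, G_new, match_tol_um=2.0)
    removed_nodes = set(skel.nodes.loc[skel.nodes["tree_id"] == trees[0], "id"])
    lost_edges = set(map(frozenset, cm.lost))
    expected = {frozenset((u, v)) for u, v in G_ref.edges
                if u in removed_nodes or v in removed_nodes}
    assert lost_edges == expected
    assert not cm.gained
    # partition invariants: each side counted exactly once
    assert len(cm.stable_ref) + len(cm.lost) == G_ref.number_of_edges()
    assert len(cm.stable_new) + len(cm.gained) == G_new.number_of_edges()


def test_added_tree_reported_gained(tiny_config):
    skel = synthetic.generate_fiber_forest(tiny_config, 4)
    trees = list(skel.tree_ids)
    reduced = skel.subset_trees(trees[1:])
    G_small = skeleton_to_graph(reduced)
    G_full = skeleton_to_graph(skel)
    cm = diff_fiber_graphs(G_small, G_full, match_tol_um=2.0)
    assert not cm.lost
    added_nodes = set(skel.nodes.loc[skel.nodes["tree_id"] == trees[0], "id"])
    gained = set(map(frozenset, cm.gained))
    expected = {frozenset((u, v)) for u, v in G_full.edges
                if u in added_nodes or v in added_nodes}
    assert gained == expected
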