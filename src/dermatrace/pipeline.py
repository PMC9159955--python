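"""End-to-end orchestration: simulate-or-load → stitch → clean → convert →
register → trace → quantify, with a single master seed and a replayable
report.

Per-stage seeds are derived deterministically from the master seed by hashing
the stage name and session label, so adding stages never perturbs earlier
ones.  Every stage's parameters and seeds are recorded in the report JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import af_removal, normalization, quantify, registration, synthetic, tracing
from .core import ImageStack, PipelineError, derive_seed


@dataclass
class SessionSpec:
    """One imaging session: either a simulation change-spec or tile paths."""
    label: str
    change: synthetic.ChangeSpec | None = None   # None for the baseline session
    tile_paths: list | None = None               # load mode: four quadrant TIFFs
    stack_path: str | None = None                # load mode: pre-stitched stack


@dataclass
class PipelineConfig:
    sessions: list
    baseline: str
    seed: int = 0
    output_dir: str | None = None
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig)
    use_tiles: bool = False                      # simulate 4-tile acquisition + stitching
    overlap_px: int | None = None
    segmentation: af_removal.SegmentationParams = field(
        default_factory=af_removal.SegmentationParams)
    conversion: normalization.ConversionParams = field(
        default_factory=normalization.ConversionParams)
    tracing: tracing.TraceParams = field(default_factory=tracing.TraceParams)
    caliber_threshold_um: float = 0.8
    trim_fraction: float = 0.7
    tps_regularization: float = 1.0
    boundary_margin_um: float = 3.0
    roi_margin_um: float = 3.0

    def __post_init__(self):
        if not self.sessions:
            raise PipelineError("session manifest is empty")
        labels = [s.label for s in self.sessions]
        if self.baseline not in labels:
            raise PipelineError(f"baseline {self.baseline!r} not in manifest {labels}")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    report: dict
    graphs: list
    transforms: list


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full longitudinal workflow on a session manifest."""
    report = {"seed": config.seed, "sessions": [], "stages": {}}
    sim = config.simulation
    base_idx = [s.label for s in config.sessions].index(config.baseline)

    # ---------------------------------------------------------------- input
    stacks16, gt_labels, scenes = [], [], []
    baseline_scene = None
    for spec in config.sessions:
        if spec.stack_path or spec.tile_paths:
            stack = _load_session(spec)
            stacks16.append(stack)
            gt_labels.append(None)
            scenes.append(None)
            report["sessions"].append({"label": spec.label, "source": "files"})
            continue
        sim_seed = derive_seed(config.seed, "simulate", spec.label)
        if spec.change is None:
            scene = synthetic.make_baseline_scene(sim, derive_seed(config.seed, "forest"))
            baseline_scene = scene
        else:
            if baseline_scene is None:
                raise PipelineError("baseline session must precede change sessions")
            scene = synthetic.apply_longitudinal_change(baseline_scene, spec.change,
                                                        sim_seed)
        frame_skel = synthetic.deformed_skeleton(scene, sim)
        stack, labels = synthetic.render_stack(frame_skel, sim,
                                               derive_seed(config.seed, "render", spec.label))
        stack.session = spec.label
        if config.use_tiles:
            stack = _through_tiles(stack, sim, config)
        stacks16.append(stack)
        gt_labels.append(labels)
        scenes.append(scene)
        report["sessions"].append({"label": spec.label, "source": "simulated",
                                   "seed": sim_seed,
                                   "change": asdict(spec.change) if spec.change else None})

    # ------------------------------------------------------- segment / clean
    cleaned16, pred_labels, trace_masks = [], [], []
    for spec, st in zip(config.sessions, stacks16):
        seeds = af_removal.auto_seed(st, config.segmentation,
                                     epidermal_hint_um=sim.epidermal_boundary_um)
        labels, tmask = af_removal.semi_supervised_segment(
            st, seeds, config.segmentation, return_trace_mask=True)
        cleaned16.append(af_removal.remove_autofluorescence(st, labels))
        pred_labels.append(labels)
        trace_masks.append(tmask)
    report["stages"]["segmentation"] = asdict(config.segmentation)

    # ------------------------------------------------------ convert 16→8 bit
    stacks8 = normalization.cross_session_normalize(cleaned16, config.conversion,
                                                    reference_index=base_idx)
    report["stages"]["conversion"] = asdict(config.conversion)

    # point clouds and tracing operate on the segmented fiber mask: the
    # cleaned 8-bit stacks are for inspection/export, while the fiber class
    # already isolates the structures of interest
    mask_stacks = [ImageStack(tm.astype(np.uint8) * 255, st.voxel_size, st.session)
                   for tm, st in zip(trace_masks, stacks16)]

    # ------------------------------------------------------------- register
    clouds = [registration.extract_point_cloud(
        s, threshold=127, max_points=15000,
        seed=derive_seed(config.seed, "cloud", spec.label))
        for spec, s in zip(config.sessions, mask_stacks)]
    transforms = []
    for i, (spec, cloud) in enumerate(zip(config.sessions, clouds)):
        if i == base_idx or cloud.empty_flag or clouds[base_idx].empty_flag:
            transforms.append(registration.CompositeTransform(
                registration.RigidTransform.identity()))
            continue
        tf, icp = registration.register_point_clouds(
            cloud, clouds[base_idx], trim_fraction=config.trim_fraction,
            tps_regularization=config.tps_regularization)
        transforms.append(tf)
    report["stages"]["registration"] = {
        "trim_fraction": config.trim_fraction,
        "tps_regularization": config.tps_regularization}

    # ---------------------------------------------------------------- trace
    graphs = []
    for spec, s8, tf in zip(config.sessions, mask_stacks, transforms):
        G = tracing.trace_fibers(s8.with_data(s8.data > 127), config.tracing)
        G = tracing.classify_fiber_caliber(G, config.caliber_threshold_um)
        _transform_graph(G, tf)
        graphs.append(G)
    report["stages"]["tracing"] = asdict(config.tracing)

    # -------------------------------------------------------------- quantify
    surface = _baseline_surface(pred_labels[base_idx], stacks16[base_idx], sim)
    roi = _common_roi(stacks8, transforms, config.roi_margin_um)
    metrics = quantify.longitudinal_metrics(graphs, base_idx, roi, surface,
                                            config.boundary_margin_um)
    for m, spec in zip(metrics, config.sessions):
        m.session = spec.label
    table = quantify.metrics_table(metrics)
    report["common_roi_um"] = [list(map(float, roi[0])), list(map(float, roi[1]))]

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return PipelineResult(table, report, graphs, transforms)


def _load_session(spec: SessionSpec) -> ImageStack:
    from .stitching import stitch_quadrants
    if spec.stack_path:
        p = Path(spec.stack_path)
        if not p.exists():
            raise PipelineError(f"session {spec.label!r}: missing input {p}")
        st = ImageStack.load(p)
        st.session = spec.label
        return st
    tiles = []
    for tp in spec.tile_paths:
        p = Path(tp)
        if not p.exists():
            raise PipelineError(f"session {spec.label!r}: missing input {p}")
        tiles.append(ImageStack.load(p))
    sup = stitch_quadrants(tiles)
    sup.stack.session = spec.label
    return sup.stack


def _through_tiles(stack: ImageStack, sim, config) -> ImageStack:
    from .stitching import stitch_quadrants
    nx_ = stack.shape[2]
    overlap = config.overlap_px if config.overlap_px is not None else \
        max(2, int(round(0.1 * nx_ / 1.9)))
    if (nx_ + overlap) % 2:
        overlap += 1
    tiles = synthetic.make_quadrant_tiles(stack, overlap)
    return stitch_quadrants(tiles).stack


def _transform_graph(G, tf):
    for n, d in G.nodes(data=True):
        d["pos"] = tf.apply(d["pos"])[0]
    for u, v, d in G.edges(data=True):
        d["path"] = tf.apply(d["path"])


def _baseline_surface(labels, stack16, sim):
    try:
        return quantify.estimate_epidermal_boundary(labels, stack16.voxel_size)
    except quantify.BoundaryEstimationError:
        return quantify.estimate_epidermal_boundary(
            None, stack16.voxel_size, metadata_depth_um=sim.epidermal_boundary_um,
            lateral_shape=stack16.shape[1:])


def _common_roi(stacks8, transforms, margin_um):
    los, his = [], []
    for st, tf in zip(stacks8, transforms):
        lo, hi = registration._transformed_bounds(st, tf)
        los.append(lo)
        his.append(hi)
    lo = np.max(los, axis=0) + margin_um
    hi = np.min(his, axis=0) - margin_um
    return (tuple(lo), tuple(hi))


def make_sni_timeline(n_regrow_steps: int = 3,
                      epidermal_entry: bool = False) -> list[SessionSpec]:
    """Standard simulated spared-nerve-injury timeline: baseline → complete
    denervation → staged thin-fiber regrowth retracing the original
    trajectories (thick fibers never regrow; epidermal entry suppressed)."""
    sessions = [SessionSpec("baseline"),
                SessionSpec("denervated", synthetic.ChangeSpec(
                    remove_frac_thin=1.0, remove_frac_thick=1.0))]
    fracs = np.linspace(0, 1, n_regrow_steps + 1)[1:]
    for i, f in enumerate(fracs):
        sessions.append(SessionSpec(
            f"regrow_{int(round(100 * f))}",
            synthetic.ChangeSpec(remove_frac_thin=1.0, remove_frac_thick=1.0,
                                 regrow_frac_thin=float(f), regrow_frac_thick=0.0,
                                 epidermal_entry=epidermal_entry)))
    return sessions
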