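"""Shared fixtures: small simulated scenes reused across the suite.

Expensive artifacts (a segmented validation scene, the five-session
longitudinal pipeline run) are session-scoped so each is computed once.
"""

import numpy as np
import pandas as pd
import pytest

from dermatrace import synthetic
from dermatrace.core import Skeleton, derive_seed


VALIDATION_DIMS = (192, 192, 48)   # the package's standard validation scene
VALIDATION_SEED = 7


@pytest.fixture(scope="session")
def validation_config():
    return synthetic.SimulationConfig(volume_dims=VALIDATION_DIMS)


@pytest.fixture(scope="session")
def validation_scene(validation_config):
    """Baseline forest + rendered stack + ground-truth labels."""
    scene = synthetic.make_baseline_scene(
        validation_config, derive_seed(VALIDATION_SEED, "forest"))
    skel = synthetic.deformed_skeleton(scene, validation_config)
    stack, labels = synthetic.render_stack(
        skel, validation_config, derive_seed(VALIDATION_SEED, "render", "baseline"))
    return dict(scene=scene, skeleton=skel, stack=stack, labels=labels,
                config=validation_config)


@pytest.fixture(scope="session")
def segmented_scene(validation_scene):
    """Automatic seeding + semi-supervised segmentation of the baseline scene."""
    from dermatrace import af_removal
    cfg = validation_scene["config"]
    seeds = af_removal.auto_seed(validation_scene["stack"],
                                 epidermal_hint_um=cfg.epidermal_boundary_um)
    labels, trace_mask = af_removal.semi_supervised_segment(
        validation_scene["stack"], seeds, return_trace_mask=True)
    return dict(seeds=seeds, pred=labels, trace_mask=trace_mask,
                **validation_scene)


@pytest.fixture(scope="session")
def sni_pipeline_result():
    """Five-session simulated spared-nerve-injury timeline, end to end."""
    from dermatrace import pipeline
    cfg = pipeline.PipelineConfig(
        sessions=pipeline.make_sni_timeline(3),
        baseline="baseline", seed=VALIDATION_SEED,
        simulation=synthetic.SimulationConfig(volume_dims=VALIDATION_DIMS))
    return pipeline.run_pipeline(cfg)


def straight_tube_skeleton(length_um=100.0, radius=0.35, y=20.0, z=30.0,
                           x0=5.0, step=1.5, boundary=15.0):
    n = int(round(length_um / step)) + 1
    rows = [(i, i - 1 if i > 0 else -1, x0 + step * i, y, z, radius, 0, "thin")
            for i in range(n)]
    df = pd.DataFrame(rows, columns=["id", "parent", "x", "y", "z",
                                     "radius", "tree_id", "caliber"])
    return Skeleton(df, boundary)


@pytest.fixture
def tube_render():
    """Noiseless render of one straight 100.5 µm tube."""
    skel = straight_tube_skeleton()
    cfg = synthetic.SimulationConfig(
        volume_dims=(256, 96, 48), af_intensity=0.0, appendage_density=0.0,
        n_trees_thin=0, n_trees_thick=0,
        noise=synthetic.NoiseParams(poisson_scale=0.0, gauss_sigma=0.0))
    stack, labels = synthetic.render_stack(skel, cfg, 0)
    return dict(skeleton=skel, config=cfg, stack=stack, labels=labels)


@pytest.fixture
def tiny_config():
    return synthetic.SimulationConfig(volume_dims=(64, 64, 32),
                                      epidermal_band=(0.0, 10.0),
                                      n_trees_thin=2, n_trees_thick=1)
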