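"""Shared fixtures: one small rendered scene reused across test modules."""

import numpy as np
import pytest

from phenopot.detection import DetectionConfig
from phenopot.pipeline import evaluate_against_truth, run_pipeline
from phenopot.synthetic import SceneConfig, default_varieties, generate_scene

SMALL_SCALE = 2.134          # mm/px — half the sensor resolution, for speed


@pytest.fixture(scope="session")
def small_scene():
    """2×2 pot grid, 3 time points, overlapping frames."""
    cfg = SceneConfig(mm_per_px=SMALL_SCALE, grid_rows=2, grid_cols=2,
                      spacing_mm=400.0, frame_px=512, overlap=0.5,
                      canvas_px=1024, days=(0, 17, 34), seed=7)
    varieties = default_varieties(4, seed=7)
    frames, gt = generate_scene(cfg, varieties)
    return cfg, varieties, frames, gt


@pytest.fixture(scope="session")
def small_pipeline(small_scene):
    """The small scene pushed through the full default pipeline."""
    cfg, _varieties, frames, gt = small_scene
    result = run_pipeline(frames, gt.layout(),
                          det_cfg=DetectionConfig(
                              pot_diameter_mm=cfg.pot_diameter_mm),
                          overlap=cfg.overlap)
    evaluation = evaluate_against_truth(result, gt, frames=frames)
    return result, evaluation


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
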