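"""Shared fixtures.

The expensive piece is the desk-scale overfit run: 8 synthetic scenes at
96×96 (the smallest size whose 3×3 patches still satisfy the backbone's
32-px minimum), trained once per session and reused by every test that
needs a trained network.
"""

from __future__ import annotations

import numpy as np
import pytest

import flowernet as fn

# desk-scale overfit study conditions (see docs/methods.md)
OVERFIT_N_SCENES = 8
OVERFIT_SIZE = 96
OVERFIT_COUNT_RANGE = (10, 25)
OVERFIT_SPACING = 5.0
OVERFIT_EPOCHS = 60
OVERFIT_SCENE_SEED = 11
OVERFIT_TRAIN_SEED = 7


def make_overfit_scenes(scene_seed: int = OVERFIT_SCENE_SEED):
    spec = fn.SceneSpec(height=OVERFIT_SIZE, width=OVERFIT_SIZE,
                        flower_spacing_min=OVERFIT_SPACING)
    return fn.generate_scenes(OVERFIT_N_SCENES, spec,
                              count_range=OVERFIT_COUNT_RANGE,
                              seed=scene_seed)


def run_overfit(scene_seed: int = OVERFIT_SCENE_SEED,
                train_seed: int = OVERFIT_TRAIN_SEED,
                epochs: int = OVERFIT_EPOCHS):
    scenes = make_overfit_scenes(scene_seed)
    data = [(s.image, s.points) for s in scenes]
    cfg = fn.TrainConfig(epochs=epochs, seed=train_seed)
    model, log = fn.train_model(data, cfg)
    return model, log, scenes


@pytest.fixture(scope="session")
def overfit_run():
    """(model, per-epoch log, scenes) from the session's one training run."""
    return run_overfit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_scene():
    spec = fn.SceneSpec(height=96, width=96, n_flowers=15,
                        flower_spacing_min=5.0, seed=42)
    return fn.generate_scene(spec)
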