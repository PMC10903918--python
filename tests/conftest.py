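"""Shared fixtures: small synthetic scenes and one trained model.

The trained model is session-scoped because training — even at reduced
tile size and depth — dominates the suite's runtime; every test that
needs a competent model shares the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

import spinequant as sq
from spinequant.training import AugmentConfig, TrainConfig, train_model


def make_entries(seeds, **spec_kwargs):
    """In-memory training manifest entries for the given scene seeds."""
    entries = []
    for s in seeds:
        spec = sq.SceneSpec(seed=s, **spec_kwargs)
        gt = sq.generate_scene(spec)
        entries.append({
            "raw": sq.render_stack(gt, spec),
            "spines": gt.spine_mask,
            "dendrites": gt.dendrite_mask,
            "voxel_size_um": spec.voxel_size,
        })
    return entries


LIGHT_AUGMENT = AugmentConfig(p_rot_small=0.3, p_noise=0.3,
                              p_brightness=0.3, p_contrast=0.3)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic scene with its ground truth (3 spines, 48² planes)."""
    spec = sq.SceneSpec(seed=7, stack_shape=(6, 48, 48), n_spines=3)
    return spec, sq.generate_scene(spec)


@pytest.fixture(scope="session")
def trained_model_e2e():
    """A dual-decoder model trained on 20 synthetic scenes.

    Scaled-down study conditions: F=8, depth 3, 48 px tiles, 24 epochs of
    70 steps at batch 8 with light augmentation — long enough to run well
    into the decayed-learning-rate regime so the late losses settle.
    """
    entries = make_entries(range(100, 120))
    cfg = TrainConfig(tile_size=48, batch_size=8, epochs=24, steps_per_epoch=70,
                      seed=0, lr0=3e-3, augment=LIGHT_AUGMENT)
    model = sq.build_model(
        sq.ArchitectureConfig(base_filters=8, depth=3, tile_size=48), seed=0)
    model, log = train_model(model, entries, cfg)
    return model, log
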