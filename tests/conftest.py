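"""Shared fixtures: all synthetic, generated at test time.

The expensive products (the standard end-to-end session, the trained patch
classifier, the 50-bouton detection benchmark) are session-scoped so the
full suite pays for each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from boutonmap.pipeline import run_pipeline, validate_config
from boutonmap.roi import RoiConfig, make_training_patches, train_bouton_classifier
from boutonmap.stimuli import make_schedule, make_stimulus_grid
from boutonmap.synth import make_scene, render_mean_image


@pytest.fixture(scope="session")
def protocol_grid():
    """The canonical tone protocol: 1.25-80 kHz in 1/4 octaves, 20-80 dB."""
    return make_stimulus_grid(1250, 80000, 0.25, 20, 80, 20)


@pytest.fixture(scope="session")
def protocol_schedule(protocol_grid):
    return make_schedule(protocol_grid, repeats=9, interval=45, n_blocks=3, seed=11)


@pytest.fixture(scope="session")
def trained_classifier():
    cfg = RoiConfig()
    patches, labels = make_training_patches(300, cfg.patch_size, seed=0)
    return train_bouton_classifier(patches, labels, seed=0, config=cfg)


@pytest.fixture(scope="session")
def detection_benchmark():
    """50 well-separated boutons at SNR 5 plus the noisy mean image."""
    scene = make_scene(shape=(256, 256), n_boutons=50, min_separation_px=12,
                       seed=3, noise_floor=0, noise_gain=0)
    noise_sd = scene.brightness.min() / 5.0  # SNR >= 5 for every bouton
    image = render_mean_image(scene, noise_sd=noise_sd, seed=4)
    return scene, image


@pytest.fixture(scope="session")
def standard_session(tmp_path_factory):
    """The standard synthetic session run end-to-end at the default
    configuration (full 25x4 grid, 3 repeats, drifting noisy movie)."""
    out = tmp_path_factory.mktemp("session")
    return run_pipeline(validate_config({"seed": 7}), out_dir=out)


@pytest.fixture
def small_config():
    """A seconds-scale configuration for pipeline contract tests."""
    return {
        "seed": 5,
        "grid": {"f_min_hz": 4000.0, "f_max_hz": 32000.0, "step_octaves": 0.5},
        "schedule": {"repeats": 2, "interval": 20, "n_blocks": 1},
        "scene": {"shape": [64, 64], "n_boutons": 6, "drift_amplitude_px": 0.0},
        "signal": {"window_frames": 15},
    }
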