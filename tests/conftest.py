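"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from membratrack import SceneParams, generate_scene


@pytest.fixture(scope="session")
def static_scene49():
    """Noise-free, motion-free 49-cell reference epithelium (1 frame)."""
    params = SceneParams(
        n_cells=49,
        n_frames=1,
        noise_sigma=0.0,
        drift_px_per_frame=(0.0, 0.0),
        jitter_px=0.0,
    )
    return generate_scene(params, seed=1)


@pytest.fixture(scope="session")
def noisy_scene49():
    """Same mosaic statistics with Gaussian read noise sigma = 0.05."""
    params = SceneParams(
        n_cells=49,
        n_frames=1,
        noise_sigma=0.05,
        drift_px_per_frame=(0.0, 0.0),
        jitter_px=0.0,
    )
    return generate_scene(params, seed=1)


@pytest.fixture(scope="session")
def drifting_scene():
    """20-frame scene with the default rightward drift and jitter."""
    return generate_scene(SceneParams(), seed=2)


@pytest.fixture(scope="session")
def small_scene():
    """Cheap 9-cell scene for fast end-to-end tests."""
    params = SceneParams(
        n_cells=9,
        field_px=(128, 128),
        n_frames=4,
        drift_px_per_frame=(0.8, 0.0),
        jitter_px=0.2,
    )
    return generate_scene(params, seed=3)
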