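"""Shared fixtures and constructive helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.morphology import disk

from clecount import Frame, SimulationConfig


def place_disks(shape, centers, radius, value=1.0):
    """Binary image with filled Euclidean disks at the given centers."""
    img = np.zeros(shape, dtype=float)
    d = disk(radius).astype(float) * value
    r = radius
    for cr, cc in centers:
        img[cr - r : cr + r + 1, cc - r : cc + r + 1] += d
    return img


def full_fov(img):
    """Frame whose whole extent counts as field of view."""
    return Frame(img, fov_mask=np.ones(img.shape, dtype=bool))


@pytest.fixture
def small_sim_config():
    """Desk-scale simulator configuration for fast detection tests."""
    def make(**overrides):
        defaults = dict(frame_height=256, frame_width=256, n_frames=4, seed=0)
        defaults.update(overrides)
        return SimulationConfig(**defaults)

    return make
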