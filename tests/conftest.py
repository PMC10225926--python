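from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ctcompat import HUVolume, VoxelSpacing

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def unit_spacing() -> VoxelSpacing:
    return VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture
def ct_spacing() -> VoxelSpacing:
    """A realistic chest-CT spacing: 0.7 mm pixels, 1.5 mm slices."""
    return VoxelSpacing(0.7, 0.7, 1.5)


def make_volume(values, spacing=None) -> HUVolume:
    return HUVolume(np.asarray(values, dtype=np.float64), spacing or VoxelSpacing(1.0, 1.0, 1.0))


@pytest.fixture
def zprofile_volume(ct_spacing) -> HUVolume:
    """1x1x3 volume whose z-profile is the canonical (0, -50, 100) example."""
    return HUVolume(np.array([0.0, -50.0, 100.0]).reshape(3, 1, 1), ct_spacing)


def random_volume(rng: np.random.Generator, shape, low=-900.0, high=2000.0) -> HUVolume:
    return HUVolume(rng.uniform(low, high, size=shape), VoxelSpacing(1.0, 1.0, 1.0))
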