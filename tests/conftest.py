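"""Shared fixtures: digital phantoms and a small synthetic dome."""

import logging

import numpy as np
import pytest

from primordium3d.core_io import LabeledVolume
from primordium3d.phantoms import (  # noqa: F401  (re-exported fixtures)
    digital_ball,
    digital_box,
    digital_ellipsoid,
    stacked_boxes,
)
from primordium3d.synthetic import generate_dome_tessellation, plant_division

logging.getLogger("primordium3d").setLevel(logging.ERROR)


DOME_KW = dict(H=28.0, Rx=16.0, Ry=16.0, layer_thicknesses=(5.0, 8.0, 7.0),
               central_L2_target_volume=500.0, voxel_size=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def small_dome():
    """A fine-grid dome with a controlled central L2 cell."""
    return generate_dome_tessellation(rng_seed=1, **DOME_KW)


@pytest.fixture(scope="session")
def divided_dome(small_dome):
    """The same dome with a fresh (jitter-free) central periclinal division."""
    vol, gt = small_dome
    return plant_division(vol, gt, gt.central_L2, "periclinal",
                          f=0.5, jitter=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def coarse_dome():
    """A quick 1-µm dome for annotation-level tests."""
    return generate_dome_tessellation(
        H=26, Rx=16, Ry=16, layer_thicknesses=(5.0, 6.0, 6.0),
        central_L2_target_volume=500.0, voxel_size=(1.0, 1.0, 1.0),
        rng_seed=1)
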