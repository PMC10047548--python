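"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

from carrierscope import synthscene as sy
from carrierscope.synthscene import (
    DEFAULT_GEOMETRY,
    OpticsParams,
    SceneParams,
)


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def small_scene():
    """One microcarrier with three cells plus sub-cellular debris."""
    params = SceneParams(
        domain_um=(200, 260, 260), n_carriers=1, explicit_counts=[3],
        n_debris=8, seed=3,
    )
    return sy.sample_scene(params)


@pytest.fixture(scope="session")
def small_volume(small_scene, optics, geometry):
    """Noisy 4-channel render of the small scene (default optics)."""
    return sy.render(small_scene, optics, geometry)


@pytest.fixture(scope="session")
def small_volume_clean(small_scene, optics, geometry):
    """Noise-free render of the small scene."""
    return sy.render(small_scene, optics.noiseless, geometry)
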