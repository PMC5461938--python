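import dataclasses

import numpy as np
import pytest

from svdmarkers.images import VoxelVolume
from svdmarkers.synthetic import GeneratorConfig, SiteSpec, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """One small two-site cohort configuration used across tests."""
    return dataclasses.replace(
        GeneratorConfig(seed=20240915),
        sites=(SiteSpec(1, 6), SiteSpec(2, 4)),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(values, kind="FA", voxel_mm=(2.0, 2.0, 2.0)):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:  # convenience: pack a value list into a 3-D lattice
        cube = np.zeros((values.size, 1, 1))
        cube[:, 0, 0] = values
        values = cube
    return VoxelVolume(values, voxel_mm, kind)
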