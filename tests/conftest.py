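import numpy as np
import pytest

from carnotype.config import default_config
from carnotype.types import PeakSpec, VoxelGeometry


@pytest.fixture()
def cfg():
    return default_config()


@pytest.fixture()
def acq(cfg):
    return cfg.acquisition


@pytest.fixture()
def unit_voxel():
    return VoxelGeometry(1.0, 1.0, 1.0)


@pytest.fixture()
def water_peak():
    """The study's average shim: 25.7 Hz Lorentzian water line."""
    return PeakSpec(4.70, 1.0, 25.7, "lorentzian", "water")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
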