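import numpy as np
import pytest

from orientpool import NeuronBank, OrientationDistribution


@pytest.fixture(scope="session")
def bank():
    return NeuronBank()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vertical_standard():
    return OrientationDistribution.point_mass(90.0)


@pytest.fixture(scope="session")
def zero_standard():
    return OrientationDistribution.point_mass(0.0)
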