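import numpy as np
import pytest

from gaitdecode.headmodel import HeadModel, Montage


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage.default()


@pytest.fixture(scope="session")
def headmodel() -> HeadModel:
    return HeadModel()


@pytest.fixture(scope="session")
def homogeneous_model() -> HeadModel:
    return HeadModel(shell_conductivities=(0.33, 0.33, 0.33, 0.33))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
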