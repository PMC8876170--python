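import numpy as np
import pytest

from leukosmear.synth import SmearSynthParams, generate_smear


@pytest.fixture(scope="session")
def small_params():
    """Generator at a reduced canvas for fast unit tests."""
    return SmearSynthParams(size=160)


@pytest.fixture(scope="session")
def default_params():
    return SmearSynthParams()


@pytest.fixture(scope="session")
def leukemia_sample(default_params):
    return generate_smear(default_params, seed=3, label="leukemia")


@pytest.fixture(scope="session")
def normal_sample(default_params):
    return generate_smear(default_params, seed=3, label="normal")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
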