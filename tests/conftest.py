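import numpy as np
import pytest

from osicea import default_bundle
from osicea.params import ModelSettings, UtilityInputs


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture()
def flat_utilities():
    return UtilityInputs(u_pfs=1.0, u_pd=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)
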