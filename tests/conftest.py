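import numpy as np
import pytest

from fracbrain import ModelParameters, fixture_graphs

#: Reference positive (coexistence) equilibrium for the default parameters.
E_STAR_REFERENCE = np.array([0.596, 0.154, 0.33, 0.14, 0.1])


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()
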