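import numpy as np
import pytest

from ecbdsi import ModelParameters, IntegratorSettings


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters().validate()


@pytest.fixture()
def fast_settings() -> IntegratorSettings:
    """Coarser recording for short unit-test integrations."""
    return IntegratorSettings(dt=0.02, record_dt=0.5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20130318)
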