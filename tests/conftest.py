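import pytest
from hypothesis import settings

from liverrheo.phantom import make_phantom

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

NOISELESS = {"noise_cv": 0.0, "normal_force_sd": 0.0}


@pytest.fixture
def normal_phantom():
    """Default normal-liver phantom with noise, seed 1."""
    return make_phantom("normal", seed=1)


@pytest.fixture
def quiet_phantom():
    """Noiseless normal phantom: generator/extractor closure is exact."""
    return make_phantom("normal", dict(NOISELESS), seed=1)


@pytest.fixture
def quiet_decel_phantom():
    return make_phantom("decellularized", dict(NOISELESS), seed=1)
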