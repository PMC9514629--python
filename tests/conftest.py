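import pytest

from osteofuzz import (
    ControllerParams,
    ModelParameters,
    builtin_designs,
    generate_synthetic,
)


@pytest.fixture(scope="session")
def theta():
    """Default ground-truth parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def cparams():
    return ControllerParams()


@pytest.fixture(scope="session")
def designs():
    return builtin_designs()


@pytest.fixture(scope="session")
def noise_free_items(theta):
    """Synthetic measurements with zero noise: exact model predictions."""
    return generate_synthetic(theta, noise_cv=0.0, seed=1)
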