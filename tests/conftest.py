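import numpy as np
import pytest

from lvimm import ImmigrationSpec, LVParameters, ModelSpec


@pytest.fixture
def fig1_params() -> LVParameters:
    """Linear-response parameter set used by the deterministic scenarios."""
    return LVParameters(r=0.1, a=0.1, b=0.3, m=0.2)


@pytest.fixture
def type2_params() -> LVParameters:
    """Hyperbolic (type II) response, h = 0.1."""
    return LVParameters(r=0.1, a=0.1, b=0.3, m=0.2, h=0.1)


@pytest.fixture
def type3_params() -> LVParameters:
    """Sigmoid (type III) response, h = 0.1, alpha = 1."""
    return LVParameters(r=0.1, a=0.1, b=0.3, m=0.2, h=0.1, alpha=1.0)


@pytest.fixture
def ensemble_params() -> LVParameters:
    """Parameter set for the random-immigration ensemble protocol."""
    return LVParameters(r=0.2, a=0.1, b=0.3, m=0.2)


@pytest.fixture
def random_pulse_model(ensemble_params) -> ModelSpec:
    return ModelSpec(
        params=ensemble_params,
        prey_imm=ImmigrationSpec.random_pulse(0.001, 1.0),
        pred_imm=ImmigrationSpec.random_pulse(0.001, 1.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260904)


def random_type1_params(rng: np.random.Generator) -> LVParameters:
    """Draw a linear-response parameter set from the test grid."""
    r, a, b, m = rng.uniform(0.05, 1.0, size=4)
    return LVParameters(r=r, a=a, b=b, m=m)
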