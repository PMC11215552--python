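import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pdsp.model import ArchitectureConfig, LossConfig, ModelParameters


@pytest.fixture
def tiny_arch() -> ArchitectureConfig:
    """Smallest sensible architecture for hand-checkable math."""
    return ArchitectureConfig(
        d_drug=2,
        d_expr=2,
        latent_dim=2,
        den_hidden=(3,),
        ddn_hidden=(2,),
        san_hidden=(3,),
        dropout_rate=0.0,
    )


@pytest.fixture
def tiny_params(tiny_arch) -> ModelParameters:
    return ModelParameters.initialize(tiny_arch, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
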