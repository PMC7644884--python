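import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avdsim import ModelParameters

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def default_params() -> ModelParameters:
    """The worked-example cell: r = 5 µm, C0 = 100 mOsm/L, S = 1000 Pa,
    Pi = 1e-5 cm/s, Pw = 2e-3 cm/s, rounded RT."""
    return ModelParameters()


def draw_regime_params(rng: np.random.Generator) -> ModelParameters:
    """A random parameter set inside the C0 >> S regime (S/C0 <= 0.05)."""
    return ModelParameters(
        radius=rng.uniform(2e-4, 1e-3),
        external_osmolarity=rng.uniform(5e-5, 3e-4),
        pressure=rng.uniform(10.0, 1500.0),
        ion_permeability=rng.uniform(1e-7, 5e-5),
        water_permeability=rng.uniform(2e-4, 1e-2),
    )


@pytest.fixture
def param_sampler():
    return draw_regime_params
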