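import numpy as np
import pytest
from hypothesis import settings

from gramscreen import LUVPopulation, simulate_luv_population

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def control_pop() -> LUVPopulation:
    """A dispersed vesicle population at the assay's default conditions."""
    return simulate_luv_population(2000, seed=11)


@pytest.fixture(scope="session")
def homogeneous_pop() -> LUVPopulation:
    """Identical vesicles with identical channel counts (beta = 1 regime)."""
    n = 1500
    return LUVPopulation(
        diameters=np.full(n, 130.0),
        channel_mean=np.full(n, 60.0),
        channel_counts=np.full(n, 60),
        fluor_load=np.full(n, 1.0),
        d_mean=130.0,
        pdi=0.0,
    )
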