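import numpy as np
import pytest

from greenozone import SyntheticConfig


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """Fast domain: 20×20 coarse cells, 50 m fine cells, 10+2 days."""
    return SyntheticConfig(seed=1, domain_size_km=20.0, coarse_res_km=1.0,
                           fine_res_m=50.0, n_days=10, spinup_days=2,
                           urban_radius_km=6.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
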