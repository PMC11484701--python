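import numpy as np
import pytest

from dwisure import PhantomConfig, SigmaProfile, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 32x32 two-b-value phantom with truth, shared across tests."""
    cfg = PhantomConfig(grid_size=(32, 32), seed=42,
                        sigma_profile=SigmaProfile(sigma_min=0.02,
                                                   sigma_max=0.06))
    truth, stack = generate_phantom(cfg)
    return cfg, truth, stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
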