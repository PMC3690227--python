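import numpy as np
import pytest

from pulleyquant import SyntheticConfig, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """One 256×256 rendered field with ground truth (shared across tests)."""
    cfg = SyntheticConfig(width=256, height=256, n_rod_nuclei=14, n_round_nuclei=8, seed=7)
    return generate_image(cfg)


@pytest.fixture(scope="session")
def random_rgb():
    r = np.random.default_rng(42)
    return r.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
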