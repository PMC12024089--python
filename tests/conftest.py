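import numpy as np
import pytest

import shortscale as ss


@pytest.fixture(scope="session")
def bank():
    return ss.scl90_bank()


@pytest.fixture(scope="session")
def bifactor_1200():
    """Medium bifactor fixture shared across modules (n=1200, 90 items)."""
    spec = ss.scl90_like_spec()
    return ss.generate_responses(spec, 1200, seed=2)


@pytest.fixture(scope="session")
def block_responses_5x6():
    """Planted 5 blocks of 6 items (within 0.6, between 0.1), n=2000."""
    spec = ss.BlockSpec(block_sizes=(6, 6, 6, 6, 6), within_r=0.6, between_r=0.1)
    return spec, ss.generate_block_responses(spec, 2000, seed=3)


@pytest.fixture
def tiny_responses():
    rng = np.random.default_rng(42)
    values = rng.integers(1, 6, size=(30, 5))
    return ss.ResponseMatrix(values, [f"item_{j}" for j in range(1, 6)])
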