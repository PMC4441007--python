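import numpy as np
import pytest

from tregscreen import ScreenParams, generate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A small planted screen shared by read-only tests: 200 compounds,
    2% enhancers, one batch."""
    batches, truth = generate_screen(
        200,
        frac_enhancers=0.02,
        params=ScreenParams(plates_per_batch=5),
        seed=42,
    )
    return batches, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
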