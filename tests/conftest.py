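import numpy as np
import pytest

from destripenet.network import CorrectionModelSpec, build_model
from destripenet.simulate import (PhantomConfig, StripeSpec, build_dataset,
                                  default_angles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """12 paired samples of 32x32 sinograms (32 angles, 32-px phantoms)."""
    return build_dataset(12, 0.75, PhantomConfig(size_px=32),
                         StripeSpec(seed=3), default_angles(32))


@pytest.fixture
def tiny_model():
    """A 4-conv-layer model, fast enough for per-test training."""
    return build_model(CorrectionModelSpec(hidden_channels=8, n_res_blocks=1),
                       init_seed=0)
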