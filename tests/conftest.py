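import numpy as np
import pytest

from ppsnet.model import PeripersonalRBM


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


# A tiny network trained for a couple of epochs: big enough for learned
# structure to differ from initialisation, small enough to train in seconds.
TINY = dict(visual_n=12, n_multi=40, epochs=3, batches_per_epoch=30,
            batch_size=50, scale="reduced")


@pytest.fixture(scope="session")
def tiny_trained():
    return PeripersonalRBM(variant="constrained", **TINY).fit(seed=7)


@pytest.fixture(scope="session")
def tiny_untrained():
    model = PeripersonalRBM(variant="constrained", **{**TINY, "epochs": 1,
                                                      "batches_per_epoch": 1})
    return model.fit(seed=7)
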