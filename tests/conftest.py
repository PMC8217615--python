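import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_synth_config():
    """A small, quick generator configuration shared by extraction tests."""
    from longfission.synthgen import SynthConfig

    return SynthConfig(images_per_class=3, cells_per_image=(2, 4), canvas=(192, 192), seed=7)
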