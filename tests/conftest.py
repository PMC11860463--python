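import numpy as np
import pytest

from imvclust import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Complete labelled two-view dataset, 40 samples, well separated."""
    return generate(SyntheticSpec(n_samples=40, dims=(6, 8), separation=6.0,
                                  seed=11))


@pytest.fixture
def tiny_config():
    from imvclust import TrainConfig

    return TrainConfig(epochs=3, batch_size=64, latent_dim=16,
                       encoder_widths=(32,), generator_widths=(16,), seed=3)
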