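import numpy as np
import pytest

from medvdm import GammaSchedule, ModelConfig, init_params


@pytest.fixture(scope="session")
def schedule():
    """Default linear noise schedule, gamma 0.1 -> 1.0."""
    return GammaSchedule()


@pytest.fixture(scope="session")
def tiny_cfg():
    """A desk-scale architecture used across network/loss tests."""
    return ModelConfig(image_size=16, hidden_dim=32, score_embedding_dim=32,
                       score_layers=3, encoder_blocks=2, decoder_blocks=2,
                       latent_dim=16)


@pytest.fixture(scope="session")
def tiny_params(tiny_cfg):
    return init_params(tiny_cfg, np.random.default_rng(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def randomize_params(params, rng, scale=0.3):
    """Random (not initialization-scheme) parameter draw for structural tests."""
    from medvdm.autodiff import tree_map

    return tree_map(lambda p: rng.normal(0.0, scale, size=np.shape(p)), params)
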