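import numpy as np
import pytest

from usvgan import NetworkConfig, build_networks


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale architecture: 512-sample waveforms, few channels."""
    return NetworkConfig(
        latent_dim=4, model_size=2, num_blocks=2,
        joint_filters=16, phase_shuffle_radius=2,
    )


@pytest.fixture(scope="session")
def tiny_nets(tiny_cfg):
    return build_networks(tiny_cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
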