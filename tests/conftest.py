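import numpy as np
import pytest

from dbhnet.swin_encoder import SwinConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_swin_config():
    """Desk-scale attention config: 64×64 images, window 2, one block/stage."""
    return SwinConfig(embed_dim=16, depths=(1, 1, 1, 1), heads=(1, 2, 4, 8),
                      window=2)


def set_bn_identity(module):
    """Put every batch-norm into eval mode with identity statistics."""
    from dbhnet import nn

    module.eval()
    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.register_buffer("running_mean",
                              np.zeros_like(m.running_mean))
            m.register_buffer("running_var", np.ones_like(m.running_var))
            m.weight.data = np.ones_like(m.weight.data)
            m.bias.data = np.zeros_like(m.bias.data)
            m.eps = 0.0
    return module
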