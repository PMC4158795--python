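import numpy as np
import pytest

from hdsn.frontend import ChannelStack
from hdsn.ggd import GGDClassModel
from hdsn.layer import ChannelModels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """Two-scale, three-channel stack of moderate Gaussian responses."""
    maps = [rng.standard_normal((3, 14, 14)), rng.standard_normal((3, 10, 10))]
    return ChannelStack(maps=maps)


@pytest.fixture
def presence_models():
    """Channel models where the target scale exceeds the background scale."""
    return ChannelModels(models=[
        GGDClassModel(scale_pow_background=1.0, scale_pow_target=2.0, shape=0.5),
        GGDClassModel(scale_pow_background=0.8, scale_pow_target=1.1, shape=0.5),
        GGDClassModel(scale_pow_background=2.0, scale_pow_target=1.0, shape=0.5),
    ])
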