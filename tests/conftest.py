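import numpy as np
import pytest

from nodulecam import nn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_gap_toy(
    n_maps: int = 4,
    ndim: int = 3,
    edge: int = 6,
    kernel: int = 3,
    seed: int = 0,
    conv_relu: bool = True,
):
    """conv -> GAP -> dense toy network (float64) for CAM equivalence."""
    r = np.random.default_rng(seed)
    net = nn.Sequential(
        [
            nn.Conv(ndim, 1, n_maps, kernel, "same", relu=conv_relu,
                    rng=r, init="he", dtype=np.float64),
            nn.GlobalAveragePool(),
            nn.Dense(n_maps, 2, relu=False, rng=r, init="he", dtype=np.float64),
        ]
    )
    from nodulecam.gradcam import ToyModel

    return ToyModel(net=net, input_shape=(1,) + (edge,) * ndim)
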