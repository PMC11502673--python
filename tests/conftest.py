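import numpy as np
import pytest

from isquant import ChannelStack, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A small, fast scene: ~8-μm cell, 3-μm bead, 20 compartments."""
    return SceneSpec(
        shape=(20, 48, 48),
        voxel_size=(0.5, 0.3, 0.3),
        cell_semiaxes=(4.0, 4.0, 4.0),
        n_compartments=20,
        seed=7,
    )


def make_channel(data, voxel_size=(0.5, 0.25, 0.25), name="test"):
    return ChannelStack(name=name, data=np.asarray(data, dtype=float), voxel_size=voxel_size)


@pytest.fixture
def channel_factory():
    return make_channel
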