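import numpy as np
import pytest

from duoview import DegradationModel, RunConfig, VolumeStack, textured_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack():
    """A 10-plane 16x16 random stack with unit spacing."""
    data = np.random.default_rng(7).random((10, 16, 16))
    return VolumeStack(data=data, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def degraded_pair():
    """A 50-plane dual-view pair with symmetric degradation (crossover 24.5)."""
    from duoview import dual_view_pair

    truth = textured_phantom((50, 64, 64), seed=42)
    v1, v2, k = dual_view_pair(truth, DegradationModel(), seed=42)
    return v1, v2, k


@pytest.fixture
def aligned_config():
    """Config for pairs already expressed in the common frame."""
    return RunConfig(register="none", flip_axes=())
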