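import numpy as np
import pytest

from steerpr.datatypes import PhantomSpec, PhasingConfig
from steerpr.simulate import embed_map, forward_diffract, make_disk_aggregate


@pytest.fixture(scope="session")
def three_disk_phantom():
    spec = PhantomSpec(kind="disk_aggregate", n_particles=3, diameter_px=10, seed=7)
    return make_disk_aggregate(spec, 64)


@pytest.fixture(scope="session")
def three_disk_pattern(three_disk_phantom):
    return forward_diffract(three_disk_phantom, pad_factor=2)


@pytest.fixture(scope="session")
def three_disk_truth(three_disk_phantom):
    return embed_map(three_disk_phantom, 2).values


@pytest.fixture(scope="session")
def tiny_pattern():
    """32x32 noiseless pattern of a 2-disk phantom (cheap trials)."""
    spec = PhantomSpec(kind="disk_aggregate", n_particles=2, diameter_px=6, seed=3)
    return forward_diffract(make_disk_aggregate(spec, 16), pad_factor=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
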