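import numpy as np
import pytest

from tonguekin.fixtures import SyntheticSpec, generate_clip


def alternating_schedule(n_runs: int, dwell: int, first: str = "R"):
    order = "RL" if first == "R" else "LR"
    return tuple((order[i % 2], dwell) for i in range(n_runs))


@pytest.fixture
def simple_spec():
    """13 alternating dwells of 10 frames at 30 fps: 12 sweeps of 1/3 s."""
    return SyntheticSpec(sweep_schedule=alternating_schedule(13, 10))


@pytest.fixture
def simple_clip(simple_spec):
    return generate_clip(simple_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)
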