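import numpy as np
import pytest

from sptmotion.io import Track
from sptmotion.simulate import SimConfig, _simulate_brownian_batch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def brownian_tracks_2d(rng):
    """20 Brownian tracks of 50 steps (d=0.1, sigma=0.02), 2D."""
    cfg = SimConfig(n_steps=50, d=0.1, sigma=0.02)
    obs, _ = _simulate_brownian_batch(20, cfg, rng)
    return [Track(f"b{i}", obs[i]) for i in range(obs.shape[0])]
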