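import numpy as np
import pytest

from stimartifact import (SimConfig, simulate_session, standard_grid)


@pytest.fixture(scope="session")
def grid():
    return standard_grid()


@pytest.fixture(scope="session")
def noiseless_session(grid):
    """Noise-free, ratchet-free, unclipped session: exact ground truth."""
    cfg = SimConfig(seed=0, noise_sd=0.0, ratchet_step=0.0, clip_limit=None)
    rec, gt = simulate_session(cfg, grid)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def noisy_session(grid):
    """Default realistic session: pink noise, ratcheting, clipping."""
    cfg = SimConfig(seed=0)
    rec, gt = simulate_session(cfg, grid)
    return cfg, rec, gt
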