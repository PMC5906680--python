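import numpy as np
import pandas as pd
import pytest

from poretrack import simkit


@pytest.fixture
def acq():
    """Default acquisition: 107 nm px, 19 ms frames, 19/25 nm precision."""
    return simkit.AcquisitionConfig(rng_seed=42)


@pytest.fixture
def small_acq():
    """Small field for movie-rendering tests."""
    return simkit.AcquisitionConfig(
        rng_seed=42, field_size_px=32, frame_count=20
    )


@pytest.fixture
def planar_mixture(acq):
    """Fig-3f-style two-population planar mixture, 2000 trajectories."""
    return simkit.simulate_planar_trajectories(
        [(2.5, 0.5), (1.0, 0.5)], 0.0, 2000, acq
    )


def make_step_trace(levels, dwells):
    """Noiseless piecewise-constant trace from (level, dwell) pairs."""
    y = np.concatenate([np.full(d, float(v)) for v, d in zip(levels, dwells)])
    return pd.DataFrame({"frame": np.arange(y.size), "photons": y})
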