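import numpy as np
import pandas as pd
import pytest

from mpskit.simulate import CoIPSimConfig, MPSSimConfig


@pytest.fixture
def small_mps_config():
    """A quick-to-generate periodic configuration for unit tests."""
    return MPSSimConfig(n_segments=5, seed=11)


@pytest.fixture
def noise_free_config():
    """Degenerate noise-free case: rings become exact delta combs."""
    return MPSSimConfig(
        n_segments=3,
        background_fraction=0.0,
        ring_axial_sd=0.0,
        loc_precision=0.0,
        lateral_sd=0.0,
        phase=0.0,
        orientation=0.0,
        seed=5,
    )


@pytest.fixture
def toy_table():
    """Small canonical localization table."""
    rng = np.random.default_rng(42)
    n = 100
    return pd.DataFrame(
        {
            "x_nm": rng.uniform(0, 2000, n).round(3),
            "y_nm": rng.uniform(-100, 100, n).round(3),
            "channel": rng.integers(1, 3, n),
            "frame": np.arange(n),
        }
    )


@pytest.fixture
def coip_config():
    return CoIPSimConfig(seed=21)
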