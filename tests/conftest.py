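import numpy as np
import pandas as pd
import pytest

from trailgaze import generate_layout
from trailgaze.synth import SimulationConfig, SubjectTraits


@pytest.fixture(scope="session")
def layout_a():
    return generate_layout("A", seed=3)


@pytest.fixture(scope="session")
def layout_b():
    return generate_layout("B", seed=4)


@pytest.fixture
def noise_free_config():
    """Synthesis config with every stochastic nuisance switched off."""
    return SimulationConfig(
        lag_noise_sd_ms=0.0,
        fixed_search_count=4,
        fix_pos_jitter_deg=0.1,
    )


@pytest.fixture
def flat_traits():
    """A deterministic subject: mean traits, no guide skipping."""
    return SubjectTraits(
        "S001",
        1,
        {
            "fix_dur_mean_ms": 180.0,
            "search_rate": 4.0,
            "eye_hand_lag_ms": 800.0,
            "click_dispersion_deg": 0.0,
            "speed_factor": 1.0,
            "guide_skip_prob": 0.0,
        },
    )


def make_samples(x, y, t0=0.0, valid=None, rate_hz=1000.0):
    """Assemble a degree-space sample frame from position arrays."""
    x = np.asarray(x, dtype=float)
    n = x.size
    df = pd.DataFrame(
        {
            "t_ms": t0 + np.arange(n) * 1000.0 / rate_hz,
            "x": x,
            "y": np.asarray(y, dtype=float),
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        }
    )
    df.attrs["unit"] = "deg"
    return df
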