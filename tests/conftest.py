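import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shiftpulse.session_io import IbiLog
from shiftpulse.synthetic import SyntheticConfig, generate_session

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_random_ibi(rng: np.random.Generator, n_beats: int, gap_prob: float = 0.05) -> IbiLog:
    """A valid random IBI log with occasional detection gaps."""
    ibis = rng.uniform(0.4, 1.6, size=n_beats)
    steps = ibis.copy()
    gaps = rng.random(n_beats) < gap_prob
    steps[gaps] += rng.uniform(2.0, 30.0, size=int(gaps.sum()))
    offsets = np.cumsum(steps)
    return IbiLog(0.0, offsets, ibis)


@pytest.fixture(scope="session")
def clean_session():
    """Uncorrupted 120 s synthetic session (truth, waveform)."""
    cfg = SyntheticConfig(duration_s=120.0, dropout_fraction=0.0, seed=3)
    return generate_session(cfg)
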