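import numpy as np
import pytest

from unitmatch.io import ProbeGeometry
from unitmatch.synthetic import SimConfig, generate_session_set


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_geometry():
    """Two-column, 12-row grid, 20 um row pitch."""
    xs = [0.0, 32.0]
    ys = np.arange(12) * 20.0
    return ProbeGeometry(np.array([(x, y) for y in ys for x in xs]))


@pytest.fixture(scope="session")
def duplicated_session_set():
    """A noiseless session duplicated as two sessions (identical physics)."""
    cfg = SimConfig(
        n_neurons=30,
        n_sessions=2,
        survival=1.0,
        replace_lost=False,
        drifts=[(0.0, 0.0), (0.0, 0.0)],
        amplitude_jitter=0.0,
        snr=None,
        seed=3,
    )
    return generate_session_set(cfg)


def random_waveform(rng, n_samples=82, n_sites=24, peak=40, amp=120.0):
    """A synthetic single-unit waveform half with a clear central peak."""
    t = np.arange(n_samples, dtype=float)
    template = -np.exp(-((t - peak) ** 2) / (2 * 3.0**2))
    template += 0.4 * np.exp(-((t - peak - 9) ** 2) / (2 * 6.0**2))
    lam = 0.04
    pos = np.array([rng.uniform(0, 32), rng.uniform(60, 160)])
    return template[:, None] * (
        amp * np.exp(-lam * np.linalg.norm(
            np.array([(x, y) for y in np.arange(12) * 20.0 for x in (0.0, 32.0)]) - pos,
            axis=1,
        ))
    )[None, :]
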