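import numpy as np
import pytest

from proteodyn.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """8-channel, 2000-sample recording at 1 Hz with mixed tones + noise."""
    t = np.arange(2000)
    v = np.vstack(
        [
            np.sin(2 * np.pi * 0.01 * t + 0.3 * c) + 0.2 * rng.normal(size=2000)
            for c in range(8)
        ]
    )
    return Recording(voltages=v, sampling_rate=1.0)
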