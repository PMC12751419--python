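import numpy as np
import pytest

from cardiosynth import rhythm_preset, simulate_pair


@pytest.fixture(scope="session")
def rsr_constant_pair():
    """Clean RSR pair, constant RR = 125 samples at 125 Hz, 60 s."""
    return simulate_pair(rhythm_preset("RSR"), [125] * 60, fs=125.0,
                         seed=1, noise_frac=0.0)


@pytest.fixture(scope="session")
def rsr_variable_pair():
    """Clean RSR pair driven by a jittered schedule (~800 +/- 40 ms)."""
    rng = np.random.default_rng(7)
    schedule = np.round(rng.normal(100, 5, size=50)).astype(int)
    return simulate_pair(rhythm_preset("RSR"), schedule, fs=125.0,
                         seed=2, noise_frac=0.0)


@pytest.fixture(scope="session")
def afib_noisy_pair():
    """AFib pair with 10% parameter noise and an irregular schedule."""
    rng = np.random.default_rng(11)
    schedule = np.round(rng.normal(90, 12, size=50)).clip(min=45).astype(int)
    return simulate_pair(rhythm_preset("AFib"), schedule, fs=125.0,
                         seed=3, noise_frac=0.1)
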