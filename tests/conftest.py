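import numpy as np
import pytest

from tenssim.emg import BurstSpec, NoiseSpec, synthesize_emg


@pytest.fixture(scope="session")
def single_burst_recording():
    """One clean, well-above-threshold burst: the latency-study stimulus."""
    burst = BurstSpec(onset_times=(1.0,), durations=(0.8,), peak_amplitude=1.2)
    noise = NoiseSpec(baseline_rms=0.05)
    return synthesize_emg(burst, noise, duration=2.5, seed=101)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
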