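import numpy as np
import pytest

from radarhr import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """High-SNR 2-min single-channel recording, artifact-free."""
    cfg = SimulationConfig(duration=120.0, sampling_rate=500.0, base_hr=75.0,
                           hrv_sd=2.0, n_channels=1, channel_snr=(50.0,),
                           artifact_rate=0.0, seed=11)
    return simulate_recording(cfg, ref_jitter_ms=0.0)


@pytest.fixture(scope="session")
def noisy_recording():
    """Four-channel 5-min recording with graded SNR and artifacts."""
    cfg = SimulationConfig(duration=300.0, sampling_rate=500.0, base_hr=75.0,
                           hrv_sd=2.0, n_channels=4,
                           channel_snr=(30.0, 20.0, 15.0, 10.0),
                           artifact_rate=12.0, seed=21)
    return simulate_recording(cfg, ref_jitter_ms=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
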