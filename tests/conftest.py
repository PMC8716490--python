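import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pacfield import ArenaSpec, SynthConfig, gen_coupled_lfp

settings.register_profile(
    "pacfield",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pacfield")

FS = 2000.0


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def coupled_session():
    """Strongly coupled 8 s session (8 Hz driver, 80 Hz carrier, low noise)."""
    cfg = SynthConfig(chi=1.0, noise_sd=2.0, duration=8.0, seed=11)
    ch1, ch2 = gen_coupled_lfp(cfg)
    return cfg, ch1, ch2


@pytest.fixture(scope="session")
def uncoupled_session():
    """chi = 0 session: driver and constant-envelope carrier, default noise."""
    cfg = SynthConfig(chi=0.0, noise_sd=10.0, duration=8.0, seed=11)
    ch1, ch2 = gen_coupled_lfp(cfg)
    return cfg, ch1, ch2


def sinusoid(freq: float, duration: float = 4.0, fs: float = FS, amp: float = 1.0):
    from pacfield import TimeSeries

    t = np.arange(int(round(duration * fs))) / fs
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), fs)
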