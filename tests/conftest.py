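import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from archpwv.mockloop import AortaSample, MockLoopConfig, modulus_for_wave_speed

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def table1_sample(length_cm: float = 36.2, wave_speed: float = 3.53,
                  slope: float = 0.01) -> AortaSample:
    """Specimen at the cohort mean characteristics with a chosen wave speed."""
    E = modulus_for_wave_speed(wave_speed, 2.0e-3, 22.8 / 2 * 1e-3, 1000.0)
    return AortaSample("MEAN", 25.4, 22.8, 16.3, 14.6, length_cm,
                       length_slope_cm_per_mmhg=slope, wall_modulus_pa=E)


@pytest.fixture
def mean_sample() -> AortaSample:
    return table1_sample()


@pytest.fixture
def quiet_config() -> MockLoopConfig:
    """Noise-free acquisition config."""
    return MockLoopConfig(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def smooth_pulse_cycle(n: int, fs: float, delay_s: float = 0.0,
                       width_frac: float = 0.25) -> np.ndarray:
    """Infinitely differentiable periodic pulse (von Mises bump)."""
    t = np.arange(n) / fs
    period = n / fs
    phase = 2 * np.pi * (t - delay_s) / period
    return np.exp(4.0 * (np.cos(phase) - 1.0) / width_frac)
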