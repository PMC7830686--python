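import numpy as np
import pytest

from ppgsleep import SimulationConfig, denoise, epochize, simulate_night

#: Low-rate, low-noise simulation settings used across tests: 32 Hz fully
#: resolves the pulse band while keeping the O(N^2) nonlinear features fast.
LOW_NOISE = dict(sampling_rate=32.0, noise_sd=0.02, powerline_amp=0.0)


def make_pulse_train(fs: float, duration_s: float, rr: float = 1.0) -> np.ndarray:
    """Noiseless train of two-Gaussian pulse templates at a fixed beat
    interval, for detector and denoiser tests."""
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.zeros_like(t)
    n_beats = int(np.ceil(duration_s / rr)) + 1
    for k in range(n_beats):
        onset = k * rr
        x += np.exp(-0.5 * ((t - (onset + 0.3 * rr)) / (0.08 * rr)) ** 2)
        x += 0.35 * np.exp(-0.5 * ((t - (onset + 0.65 * rr)) / (0.12 * rr)) ** 2)
    return x


@pytest.fixture(scope="session")
def small_night():
    """A 40-epoch low-noise synthetic night shared across tests."""
    return simulate_night(SimulationConfig(epochs_per_night=40, seed=7, **LOW_NOISE))


@pytest.fixture(scope="session")
def small_epochs(small_night):
    clean = denoise(small_night.samples, small_night.sampling_rate)
    return epochize(clean, hypnogram=small_night.hypnogram,
                    sampling_rate=small_night.sampling_rate)
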