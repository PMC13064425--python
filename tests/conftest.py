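import numpy as np
import pytest

from lfpspec import (
    SimulationSpec,
    build_target_log_spectrum,
    simulate_time_series,
    welch_psd,
)
from lfpspec.core import PowerSpectrum


@pytest.fixture(scope="session")
def peakless_psd() -> PowerSpectrum:
    """Welch spectrum of a 600 s pure 1/f^1.2 trace (60 dB at 1 Hz)."""
    ts = simulate_time_series(SimulationSpec(duration=600.0, seed=0))
    return welch_psd(ts, window_seconds=3.0, nfft=4000)


@pytest.fixture(scope="session")
def theta_psd() -> PowerSpectrum:
    """Welch spectrum of the hardest theta condition (cf 6 Hz, bw 5 Hz)."""
    from lfpspec.benchmark import theta_template
    from lfpspec.preprocess import remove_noise_peak

    ts = simulate_time_series(theta_template(6.0, 5.0, seed=7))
    ps = welch_psd(ts, window_seconds=3.0, nfft=4000)
    for center in (50.0, 150.0):
        ps = remove_noise_peak(ps, center)
    return ps


@pytest.fixture()
def analytic_grid() -> np.ndarray:
    """Quarter-Hz frequency grid from 1 to 500 Hz (the Welch grid)."""
    return np.arange(1.0, 500.01, 0.25)


@pytest.fixture()
def one_exp_curve(analytic_grid):
    """Noiseless 1/f^1.2 log-spectrum anchored at 60 dB."""
    spec = SimulationSpec(duration=10.0, seed=0)
    return PowerSpectrum(analytic_grid, build_target_log_spectrum(spec, analytic_grid))
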