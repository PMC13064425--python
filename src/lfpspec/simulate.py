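"""Synthetic wide-band LFP generator.

Time series are produced by spectrally shaping Gaussian white noise: the FFT
of a white trace is multiplied, bin by bin, by the square root of the ratio
between a prescribed target power density and the white-noise density, and
inverted back to the time domain.  The expected Welch spectrum of the output
therefore equals the target spectrum: a 1/f^n aperiodic background (anchored
by the power at 1 Hz, in dB) plus Gaussian bumps in log10-power standing in
for hippocampal oscillations (theta, slow gamma) and for narrow line-noise
peaks at 50 and 150 Hz.

The aperiodic background may alternatively be any callable returning log10
power over frequency (e.g. the ``evaluate`` method of a fitted multi-knee
aperiodic model), which makes ground-truth parameter-recovery experiments
for the knee models possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import TimeSeries

__all__ = [
    "SpectralPeakSpec",
    "SimulationSpec",
    "LINE_NOISE_PEAKS",
    "build_target_log_spectrum",
    "simulate_time_series",
]

logger = logging.getLogger(__name__)

#: Narrow electronic noise peaks: 2.5 dB high, 0.5 Hz bandwidth (std 0.25 Hz),
#: centered at 50 Hz and at 150 Hz.
LINE_NOISE_PEAKS: tuple["SpectralPeakSpec", ...]


@dataclass(frozen=True)
class SpectralPeakSpec:
    """One Gaussian bump in the log10-power spectrum.

    ``height_db`` is measured in dB above the aperiodic curve at the center
    frequency; since spectra are handled as log10 power, the bump height in
    log10 units is ``height_db / 10``.  The conventional bandwidth is
    ``2 * std``.
    """

    center_freq: float
    height_db: float
    std: float

    def __post_init__(self) -> None:
        if not (self.center_freq > 0):
            raise ValueError(f"center_freq must be positive, got {self.center_freq}")
        if not (self.std > 0):
            raise ValueError(f"std must be positive, got {self.std}")
        if not np.isfinite(self.height_db):
            raise ValueError("height_db must be finite")

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.std

    def log10_curve(self, freqs: np.ndarray) -> np.ndarray:
        """Gaussian bump evaluated in log10-power units."""
        return (self.height_db / 10.0) * np.exp(
            -((freqs - self.center_freq) ** 2) / (2.0 * self.std**2)
        )


LINE_NOISE_PEAKS = (
    SpectralPeakSpec(center_freq=50.0, height_db=2.5, std=0.25),
    SpectralPeakSpec(center_freq=150.0, height_db=2.5, std=0.25),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one synthetic LFP trace.

    Defaults mirror the simulation study this package validates against: a
    1/f^1.2 background with 60 dB of power at 1 Hz, sampled at 1 kHz for
    600 s.  Oscillatory bumps and line-noise peaks are opt-in.

    ``base_noise_sigma`` adds an optional white measurement-noise floor
    (standard deviation, in the same arbitrary voltage units as the trace)
    on top of the shaped signal; the default of 0 keeps the spectrum exactly
    on the prescribed curve.

    ``background`` optionally replaces the single-exponent background with
    an arbitrary log10-power curve (a callable of frequency, e.g. a fitted
    aperiodic model's ``evaluate``); ``aperiodic_exponent`` and
    ``power_at_1hz`` are then ignored.
    """

    duration: float = 600.0
    sampling_rate: float = 1000.0
    aperiodic_exponent: float = 1.2
    power_at_1hz: float = 60.0
    peaks: tuple[SpectralPeakSpec, ...] = ()
    noise_peaks: tuple[SpectralPeakSpec, ...] = ()
    base_noise_sigma: float = 0.0
    seed: int = 0
    background: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(
                "duration * sampling_rate must be a positive integer, "
                f"got {n}"
            )
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be non-negative")
        if self.base_noise_sigma < 0:
            raise ValueError("base_noise_sigma must be non-negative")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "noise_peaks", tuple(self.noise_peaks))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def all_peaks(self) -> tuple[SpectralPeakSpec, ...]:
        return self.peaks + self.noise_peaks


def build_target_log_spectrum(spec: SimulationSpec, freqs: Sequence[float]) -> np.ndarray:
    """Evaluate the prescribed log10-power spectrum on a frequency grid.

    The aperiodic part is ``offset - n * log10(f)`` with the offset chosen so
    that the value at 1 Hz equals ``power_at_1hz / 10`` log10 units (dB are
    10 * log10 power); each peak adds a Gaussian bump in log10 power.

    Raises
    ------
    ValueError
        If any frequency is non-positive.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    if f.ndim == 1 and f.size > 1 and np.any(np.diff(f) < 0):
        raise ValueError("frequencies must be sorted in increasing order")
    if spec.background is not None:
        target = np.asarray(spec.background(f), dtype=float)
    else:
        offset = spec.power_at_1hz / 10.0
        target = offset - spec.aperiodic_exponent * np.log10(f)
    for peak in spec.all_peaks:
        target = target + peak.log10_curve(f)
    return target


def simulate_time_series(spec: SimulationSpec) -> TimeSeries:
    """Generate one trace whose expected Welch spectrum is the target curve.

    Gaussian white noise is transformed with a real FFT, each positive
    frequency bin is scaled by sqrt(target density / white density), the DC
    bin is zeroed, and the result is inverted (the inverse real FFT enforces
    Hermitian symmetry, so the output is exactly real).  Below 1 Hz the
    target is held at its 1 Hz value so that the 1/f^n divergence cannot
    dominate the trace; the spectral range that matters (1 Hz to Nyquist) is
    shaped exactly.

    Identical specs (including the seed) yield bit-identical traces.

    Raises
    ------
    ValueError
        If the duration is too short to resolve a 1 Hz frequency spacing.
    """
    n = spec.n_samples
    fs = spec.sampling_rate
    if 1.0 / spec.duration > 1.0:
        raise ValueError(
            f"duration {spec.duration} s gives frequency spacing "
            f"{1.0 / spec.duration:.3g} Hz > 1 Hz; use a longer trace"
        )
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    coeffs = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    # one-sided density of unit-variance white noise is 2/fs
    target_log = build_target_log_spectrum(spec, np.maximum(freqs[1:], 1.0))
    gain = np.empty_like(freqs)
    gain[0] = 0.0
    gain[1:] = np.sqrt(np.power(10.0, target_log) / (2.0 / fs))
    samples = np.fft.irfft(coeffs * gain, n)
    if spec.base_noise_sigma > 0:
        samples = samples + spec.base_noise_sigma * rng.standard_normal(n)
    return TimeSeries(samples, fs)
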