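"""Shared containers: uniformly sampled voltage traces and log10 power spectra.

Everything downstream (fitting, peak detection, iteration) operates on
:class:`PowerSpectrum`, which stores frequency in Hz against log10 power
spectral density.  :class:`TimeSeries` carries the simulator output and the
preprocessing input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries", "PowerSpectrum"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Real-valued voltage samples (arbitrary units, uV-like).
    sampling_rate
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("samples must not be empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.sampling_rate > 0):
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sampling_rate", float(self.sampling_rate))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    def __len__(self) -> int:
        return self.n_samples


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power spectrum stored as log10 density over frequency.

    ``freqs`` must be strictly increasing and strictly positive (the DC bin
    is never stored, since log10 power is undefined there).
    """

    freqs: np.ndarray
    log_power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        log_power = np.asarray(self.log_power, dtype=float)
        if freqs.ndim != 1 or log_power.ndim != 1:
            raise ValueError("freqs and log_power must be 1-D")
        if freqs.size != log_power.size:
            raise ValueError(
                f"length mismatch: {freqs.size} freqs vs {log_power.size} powers"
            )
        if freqs.size == 0:
            raise ValueError("spectrum must contain at least one bin")
        if not np.all(np.isfinite(freqs)) or not np.all(np.isfinite(log_power)):
            raise ValueError("spectrum contains non-finite values")
        if freqs[0] <= 0:
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "log_power", log_power)

    def band_mask(self, fmin: float, fmax: float, open_interval: bool = False) -> np.ndarray:
        """Boolean mask of bins inside [fmin, fmax] (or (fmin, fmax) if open)."""
        if open_interval:
            return (self.freqs > fmin) & (self.freqs < fmax)
        return (self.freqs >= fmin) & (self.freqs <= fmax)

    def restrict(self, fmin: float, fmax: float) -> "PowerSpectrum":
        """Return the sub-spectrum with fmin <= f <= fmax."""
        mask = self.band_mask(fmin, fmax)
        if not mask.any():
            raise ValueError(f"no frequency bins inside [{fmin}, {fmax}] Hz")
        return PowerSpectrum(self.freqs[mask], self.log_power[mask])

    def with_log_power(self, log_power: np.ndarray) -> "PowerSpectrum":
        return PowerSpectrum(self.freqs, log_power)

    def same_grid(self, other: "PowerSpectrum") -> bool:
        return self.freqs.size == other.freqs.size and np.array_equal(
            self.freqs, other.freqs
        )

    def __len__(self) -> int:
        return self.freqs.size
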