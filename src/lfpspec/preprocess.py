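"""From raw traces to cleaned power spectra.

The preprocessing chain mirrors standard tetrode LFP practice: an 8th-order
Butterworth low-pass at 500 Hz applied forward-backward (zero phase), integer
downsampling to 1 kHz, removal of low-speed epochs (below 5 cm/s for at
least 450 ms), Welch power spectral density with a Hann window, selection of
the electrode with the highest total log power between 1 and 495 Hz, and
subtraction of narrow line-noise peaks (50 Hz and harmonics) by fitting a
single exponent plus one Gaussian in a small window around each peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .core import PowerSpectrum, TimeSeries

__all__ = [
    "SpeedTrace",
    "Segment",
    "lowpass_downsample",
    "mask_low_speed",
    "welch_psd",
    "welch_psd_segments",
    "select_electrode",
    "remove_noise_peak",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeedTrace:
    """Animal running speed in cm/s, time-aligned to a voltage trace."""

    speed: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        speed = np.asarray(self.speed, dtype=float)
        if speed.ndim != 1 or speed.size == 0:
            raise ValueError("speed must be a non-empty 1-D sequence")
        if np.any(speed < 0) or not np.all(np.isfinite(speed)):
            raise ValueError("speeds must be finite and non-negative")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "speed", speed)

    @property
    def duration(self) -> float:
        return self.speed.size / self.sampling_rate


@dataclass(frozen=True)
class Segment:
    """A retained piece of a trace, with its offset in the original."""

    start_index: int
    ts: TimeSeries

    @property
    def start_time(self) -> float:
        return self.start_index / self.ts.sampling_rate


def lowpass_downsample(
    ts: TimeSeries,
    cutoff: float = 500.0,
    order: int = 8,
    target_rate: float = 1000.0,
) -> TimeSeries:
    """Zero-phase Butterworth low-pass followed by integer decimation.

    Forward-backward filtering preserves the spectral shape well below the
    cutoff (and introduces no phase distortion, which matters for the
    time-domain comparator methods).  When the input already sits at the
    critical rate (Nyquist == cutoff) there is nothing above the cutoff to
    remove and only the decimation is applied.
    """
    fs = ts.sampling_rate
    if fs < 2 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz below twice the cutoff ({2 * cutoff} Hz)"
        )
    factor = fs / target_rate
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError(
            f"target_rate {target_rate} Hz must divide the sampling rate {fs} Hz"
        )
    factor = int(round(factor))
    samples = ts.samples
    if fs > 2 * cutoff:
        sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
        samples = signal.sosfiltfilt(sos, samples)
    return TimeSeries(samples[::factor].copy(), target_rate)


def _resample_nearest(speed: SpeedTrace, n_out: int, fs_out: float) -> np.ndarray:
    # camera rate (tens of Hz) is far below the LFP rate, so nearest-neighbor
    # lookup of the closest speed sample is adequate
    t = np.arange(n_out) / fs_out
    idx = np.clip(np.round(t * speed.sampling_rate).astype(int), 0, speed.speed.size - 1)
    return speed.speed[idx]


def mask_low_speed(
    ts: TimeSeries,
    speed: SpeedTrace,
    threshold: float = 5.0,
    min_duration_ms: float = 450.0,
) -> list[Segment]:
    """Drop epochs where the animal moved below ``threshold`` cm/s for at
    least ``min_duration_ms``; return the retained segments with offsets.

    Sub-threshold runs shorter than the minimum duration are retained, so
    brief decelerations inside a movement bout do not fragment the trace.
    """
    if abs(ts.duration - speed.duration) > max(1.0 / speed.sampling_rate, 1.0 / ts.sampling_rate):
        raise ValueError(
            f"trace ({ts.duration:.3f} s) and speed ({speed.duration:.3f} s) "
            "are not time-aligned"
        )
    speed_rs = _resample_nearest(speed, ts.n_samples, ts.sampling_rate)
    below = speed_rs < threshold
    min_samples = int(np.ceil(min_duration_ms / 1000.0 * ts.sampling_rate))

    # boundaries of maximal sub-threshold runs
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    remove = np.zeros(ts.n_samples, dtype=bool)
    for lo, hi in zip(starts, stops):
        if hi - lo >= min_samples:
            remove[lo:hi] = True

    keep_padded = np.concatenate(([False], ~remove, [False]))
    kedges = np.flatnonzero(np.diff(keep_padded.astype(int)))
    segments = []
    for lo, hi in zip(kedges[::2], kedges[1::2]):
        segments.append(Segment(int(lo), TimeSeries(ts.samples[lo:hi].copy(), ts.sampling_rate)))
    return segments


def welch_psd(
    ts: TimeSeries,
    window_seconds: float = 1.2,
    nfft: int = 4000,
    overlap_fraction: float = 0.5,
) -> PowerSpectrum:
    """Welch power spectral density with a Hann window, as log10 density.

    The frequency spacing is ``sampling_rate / nfft`` (windows shorter than
    ``nfft`` are zero-padded).  The DC bin is dropped: spectra are handled in
    log10 power over strictly positive frequencies.
    """
    nperseg = int(round(window_seconds * ts.sampling_rate))
    if nperseg > ts.n_samples:
        raise ValueError(
            f"window of {window_seconds} s ({nperseg} samples) longer than the "
            f"trace ({ts.n_samples} samples)"
        )
    if nfft < nperseg:
        raise ValueError(f"nfft={nfft} smaller than the window ({nperseg} samples)")
    freqs, psd = signal.welch(
        ts.samples,
        fs=ts.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_fraction)),
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    keep = (freqs > 0) & (psd > 0)
    return PowerSpectrum(freqs[keep], np.log10(psd[keep]))


def welch_psd_segments(
    segments: Sequence[Segment | TimeSeries],
    window_seconds: float = 1.2,
    nfft: int = 4000,
    overlap_fraction: float = 0.5,
) -> PowerSpectrum:
    """Duration-weighted average of per-segment Welch spectra.

    Computing the PSD per retained segment and averaging (in linear power)
    avoids the discontinuity artifacts that concatenating masked data would
    introduce.  Segments shorter than one window are skipped with a notice.
    """
    total = None
    weight = 0.0
    freqs = None
    for seg in segments:
        ts = seg.ts if isinstance(seg, Segment) else seg
        try:
            ps = welch_psd(ts, window_seconds, nfft, overlap_fraction)
        except ValueError:
            logger.info("skipping segment shorter than one Welch window")
            continue
        if freqs is None:
            freqs = ps.freqs
            total = np.zeros_like(ps.log_power)
        elif not np.array_equal(freqs, ps.freqs):
            raise ValueError("segments produced mismatched frequency grids")
        total += ts.duration * np.power(10.0, ps.log_power)
        weight += ts.duration
    if total is None or weight == 0:
        raise ValueError("no segment long enough for one Welch window")
    return PowerSpectrum(freqs, np.log10(total / weight))


def select_electrode(
    spectra: Sequence[PowerSpectrum],
    fmin: float = 1.0,
    fmax: float = 495.0,
) -> int:
    """Index of the spectrum with the highest total log power on (fmin, fmax).

    The total is the sum of log10 power over the open interval
    ``fmin < f < fmax``; all spectra must share one frequency grid.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for ps in spectra[1:]:
        if not ref.same_grid(ps):
            raise ValueError("spectra are not on a common frequency grid")
    mask = ref.band_mask(fmin, fmax, open_interval=True)
    totals = [float(np.sum(ps.log_power[mask])) for ps in spectra]
    return int(np.argmax(totals))


def _line_model(f, b, n, h, cf, sd):
    return b - n * np.log10(f) + h * np.exp(-((f - cf) ** 2) / (2.0 * sd**2))


def remove_noise_peak(
    ps: PowerSpectrum,
    center: float,
    fit_range: tuple[float, float] | None = None,
    max_std: float = 2.0,
    min_height: float = 0.01,
) -> PowerSpectrum:
    """Subtract one narrow noise peak from the spectrum.

    A single-exponent aperiodic curve plus one Gaussian is fitted inside
    ``fit_range`` (default: center +/- 7 Hz, mirroring the 43-57 Hz window
    used for 50 Hz line noise) and only the Gaussian is subtracted, so bins
    outside the window are returned bit-identical.  The Gaussian width is
    capped at ``max_std`` Hz: line noise is narrow, and a loose width would
    let the Gaussian absorb genuine broadband structure.

    If no convincing peak is found (fitted height below ``min_height`` log10
    units, or the optimizer fails), the input is returned unchanged and a
    notice is logged.
    """
    if fit_range is None:
        fit_range = (center - 7.0, center + 7.0)
    lo, hi = fit_range
    if not (lo < center < hi):
        raise ValueError(f"fit_range {fit_range} does not contain center {center}")
    if lo < ps.freqs[0] or hi > ps.freqs[-1]:
        raise ValueError(f"fit_range {fit_range} outside spectrum support")
    mask = ps.band_mask(lo, hi)
    f = ps.freqs[mask]
    y = ps.log_power[mask]
    if f.size < 8:
        raise ValueError("fit_range contains too few bins to fit")

    slope, intercept = np.polyfit(np.log10(f), y, 1)
    resid0 = y - (intercept + slope * np.log10(f))
    i0 = int(np.argmax(resid0))
    p0 = (intercept, -slope, max(resid0[i0], 0.05), f[i0], 0.5)
    bounds = (
        [-np.inf, -8.0, 0.0, lo, 0.05],
        [np.inf, 12.0, 10.0, hi, max_std],
    )
    try:
        popt, _ = optimize.curve_fit(
            _line_model, f, y, p0=p0, bounds=bounds, maxfev=2000
        )
    except RuntimeError:
        logger.info("no detectable noise peak near %.1f Hz (fit failed)", center)
        return ps
    _, _, h, cf, sd = popt
    if h < min_height:
        logger.info("no detectable noise peak near %.1f Hz (height %.3g)", center, h)
        return ps
    cleaned = ps.log_power.copy()
    cleaned[mask] = y - h * np.exp(-((f - cf) ** 2) / (2.0 * sd**2))
    return ps.with_log_power(cleaned)
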