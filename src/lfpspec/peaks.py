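"""Band-restricted detection of periodic (oscillatory) components.

Peaks are Gaussian bumps fitted on the *flattened* spectrum (log10 power
minus the aperiodic fit).  Unlike generic multi-Gaussian spectral peak
fitting, detection here is restricted to at most one peak per
hippocampus-relevant oscillatory band, each with its own center-frequency
bounds, width limits, relative threshold (in multiples of the in-band
residual standard deviation) and absolute minimum height.  This prevents a
single brain rhythm from being split across several Gaussians and keeps the
gap frequencies between bands free of peaks.

Both aperiodic and periodic assessment start at 4 Hz, which keeps the
inconsistent hippocampal delta range out of every computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .aperiodic import AperiodicFit
from .core import PowerSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "BandConfig",
    "Peak",
    "DEFAULT_BANDS",
    "flatten",
    "detect_band_peaks",
    "subtract_peaks",
    "full_model_error",
]


@dataclass(frozen=True)
class BandConfig:
    """Detection settings for one oscillatory band."""

    name: str
    detection_range: tuple[float, float]
    cf_bounds: tuple[float, float]
    peak_width_limits: tuple[float, float]
    peak_threshold: float
    min_peak_height: float

    def __post_init__(self) -> None:
        d_lo, d_hi = self.detection_range
        c_lo, c_hi = self.cf_bounds
        w_lo, w_hi = self.peak_width_limits
        if not (d_lo < d_hi and c_lo < c_hi and w_lo < w_hi):
            raise ValueError(f"band {self.name}: intervals must be well-ordered")
        if not (d_lo <= c_lo and c_hi <= d_hi):
            raise ValueError(f"band {self.name}: cf_bounds outside detection_range")
        if w_lo <= 0:
            raise ValueError(f"band {self.name}: width limits must be positive")


#: Per-band detection parameters for rodent hippocampal LFP: detection range,
#: center-frequency bounds, peak-width (bandwidth = 2 std) limits, relative
#: threshold in units of the in-band flattened-spectrum SD, and minimum
#: accepted height in log10(psd) units.
DEFAULT_BANDS: tuple[BandConfig, ...] = (
    BandConfig("theta", (4.0, 12.0), (5.0, 9.5), (2.0, 5.0), 1.0, 0.1),
    BandConfig("sgamma", (19.0, 48.0), (25.0, 40.0), (5.0, 25.0), 1.0, 0.05),
    BandConfig("fgamma", (51.0, 90.0), (52.0, 80.0), (3.0, 35.0), 1.0, 0.08),
    BandConfig("ripples", (100.0, 200.0), (125.0, 160.0), (10.0, 30.0), 1.0, 0.05),
)


@dataclass(frozen=True)
class Peak:
    """One Gaussian periodic component on the flattened spectrum."""

    band: str
    center_freq: float
    height: float
    std: float

    def __post_init__(self) -> None:
        if not (self.center_freq > 0 and self.std > 0):
            raise ValueError("center_freq and std must be positive")

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.std

    def gaussian(self, freqs: np.ndarray) -> np.ndarray:
        return self.height * np.exp(
            -((np.asarray(freqs, dtype=float) - self.center_freq) ** 2)
            / (2.0 * self.std**2)
        )


def flatten(ps: PowerSpectrum, fit: AperiodicFit) -> PowerSpectrum:
    """Residual spectrum (data minus aperiodic curve) over the fitted range.

    The output is restricted to the fit's frequency range so that nothing
    downstream ever evaluates below the 4 Hz assessment floor.
    """
    sub = ps.restrict(*fit.freq_range)
    return sub.with_log_power(sub.log_power - fit.evaluate(sub.freqs))


def _gauss(f, h, cf, sd):
    return h * np.exp(-((f - cf) ** 2) / (2.0 * sd**2))


def _fit_band_peak(flat: PowerSpectrum, band: BandConfig) -> Peak | None:
    mask = flat.band_mask(*band.detection_range)
    if mask.sum() < 8:
        # band (almost) outside the flattened support: nothing to detect
        logger.debug("band %s not covered by the flattened spectrum; skipped", band.name)
        return None
    f = flat.freqs[mask]
    resid = flat.log_power[mask]
    sd_band = float(resid.std())
    i_max = int(np.argmax(resid))
    if resid[i_max] < band.peak_threshold * sd_band:
        return None
    if resid[i_max] < band.min_peak_height:
        # a fitted Gaussian cannot exceed the tallest residual bin by much,
        # so an under-threshold maximum cannot yield an acceptable peak
        return None
    w_lo, w_hi = band.peak_width_limits
    c_lo, c_hi = band.cf_bounds
    cf0 = float(np.clip(f[i_max], c_lo, c_hi))
    sd0 = float(np.sqrt(w_lo * w_hi) / 2.0)
    h0 = float(resid[i_max])
    bounds = ([0.0, c_lo, w_lo / 2.0], [max(2.0 * h0, 1.0), c_hi, w_hi / 2.0])
    try:
        popt, _ = optimize.curve_fit(
            _gauss, f, resid, p0=(h0, cf0, sd0), bounds=bounds, maxfev=600
        )
    except RuntimeError:
        return None
    h, cf, sd = (float(v) for v in popt)
    if h < band.min_peak_height:
        return None
    return Peak(band=band.name, center_freq=cf, height=h, std=sd)


def detect_band_peaks(
    flat: PowerSpectrum,
    bands: Sequence[BandConfig] = DEFAULT_BANDS,
    mode: str = "per_band",
) -> list[Peak]:
    """At most one Gaussian peak per band, fitted on the flattened spectrum.

    In the default ``per_band`` mode each band is processed independently: a
    candidate is accepted only if the maximum in-band residual exceeds
    ``peak_threshold`` times the in-band residual SD, and the fitted height
    reaches ``min_peak_height``; the center frequency and width are hard
    optimizer bounds, so every returned peak satisfies its band's
    constraints by construction.

    ``mode="highest_gaussian"`` is the alternative sometimes used with
    generic spectral parameterization: Gaussians are peeled greedily off the
    whole flattened spectrum and the highest one falling in each band is
    kept (subject to the same acceptance rules).  It is provided for
    comparison only.
    """
    if mode == "per_band":
        peaks = []
        for band in bands:
            peak = _fit_band_peak(flat, band)
            if peak is not None:
                peaks.append(peak)
        return peaks
    if mode == "highest_gaussian":
        return _detect_highest_gaussian(flat, bands)
    raise ValueError(f"unknown detection mode {mode!r}")


def _detect_highest_gaussian(
    flat: PowerSpectrum, bands: Sequence[BandConfig], max_peaks: int = 8
) -> list[Peak]:
    """Greedy whole-spectrum Gaussian peeling, then best-per-band selection."""
    lo = min(b.detection_range[0] for b in bands)
    hi = max(b.detection_range[1] for b in bands)
    mask = flat.band_mask(lo, hi)
    f = flat.freqs[mask]
    resid = flat.log_power[mask].copy()
    candidates: list[Peak] = []
    for _ in range(max_peaks):
        sd_all = float(resid.std())
        i_max = int(np.argmax(resid))
        if resid[i_max] < 2.0 * sd_all or resid[i_max] <= 0:
            break
        # half-height width as the initial scale
        half = resid[i_max] / 2.0
        j = i_max
        while j + 1 < f.size and resid[j] > half:
            j += 1
        sd0 = max((f[min(j, f.size - 1)] - f[i_max]) / 1.18, (f[1] - f[0]))
        try:
            popt, _ = optimize.curve_fit(
                _gauss,
                f,
                resid,
                p0=(resid[i_max], f[i_max], sd0),
                bounds=([0.0, lo, 1e-2], [np.inf, hi, hi - lo]),
                maxfev=600,
            )
        except RuntimeError:
            break
        h, cf, sd = (float(v) for v in popt)
        candidates.append(Peak(band="", center_freq=cf, height=h, std=sd))
        resid = resid - _gauss(f, h, cf, sd)
    out: list[Peak] = []
    for band in bands:
        in_band = [
            p for p in candidates
            if band.detection_range[0] <= p.center_freq <= band.detection_range[1]
        ]
        in_band = [p for p in in_band if p.height >= band.min_peak_height]
        if in_band:
            best = max(in_band, key=lambda p: p.height)
            out.append(
                Peak(band.name, best.center_freq, best.height, best.std)
            )
    return out


def subtract_peaks(ps: PowerSpectrum, peaks: Sequence[Peak]) -> PowerSpectrum:
    """Spectrum minus the summed Gaussian peaks, in log10-power units."""
    if not peaks:
        return ps
    total = np.zeros_like(ps.log_power)
    for peak in peaks:
        total += peak.gaussian(ps.freqs)
    return ps.with_log_power(ps.log_power - total)


def full_model_error(
    ps: PowerSpectrum,
    fit: AperiodicFit,
    peaks: Sequence[Peak],
    freq_range: tuple[float, float] | None = None,
) -> float:
    """Mean absolute difference between the data and aperiodic + peaks."""
    if freq_range is None:
        freq_range = fit.freq_range
    mask = ps.band_mask(*freq_range)
    if not mask.any():
        raise ValueError(f"no frequency bins inside {freq_range}")
    f = ps.freqs[mask]
    model = fit.evaluate(f)
    for peak in peaks:
        model = model + peak.gaussian(f)
    return float(np.mean(np.abs(ps.log_power[mask] - model)))
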