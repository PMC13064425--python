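"""Plain-text readers and writers.

Traces and spectra travel as diffable TSV (a ``# sampling_rate_hz:`` header
line for traces; two columns ``frequency_hz<TAB>log10_power`` for spectra,
written with 12+ significant digits so round trips are lossless at double
precision for practical purposes).  Fit results and iteration histories are
JSON with a fixed schema that records the model kind, parameters, errors,
BIC, canonicalization flag, software version and a config echo.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .aperiodic import AperiodicFit, AperiodicModelKind, AperiodicParams
from .core import PowerSpectrum, TimeSeries
from .iterate import IterationResult
from .peaks import BandConfig, Peak
from .preprocess import SpeedTrace
from .simulate import SimulationSpec, SpectralPeakSpec

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_speed",
    "read_psd",
    "write_psd",
    "fit_to_dict",
    "fit_from_dict",
    "write_result",
    "read_result",
    "history_to_dict",
    "peaks_to_dict",
    "read_simulation_spec",
    "write_simulation_spec",
    "read_band_config",
    "write_band_config",
    "validate_result",
    "RESULT_REQUIRED_KEYS",
]

_FMT = "%.12g"

RESULT_REQUIRED_KEYS = (
    "model",
    "params",
    "freq_range",
    "ap_error",
    "bic",
    "canonicalized",
    "version",
)


# ---------------------------------------------------------------------------
# traces and spectra


def _read_rate_header(lines: list[str], path: str) -> float:
    for line in lines:
        if line.startswith("#") and "sampling_rate_hz" in line:
            try:
                return float(line.split(":", 1)[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed sampling-rate header {line!r}") from exc
    raise ValueError(f"{path}: missing '# sampling_rate_hz:' header")


def _parse_column(lines: list[str], path: str, n_cols: int) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} column(s), got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {stripped!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_timeseries(path: str | Path) -> TimeSeries:
    lines = Path(path).read_text().splitlines()
    rate = _read_rate_header(lines, str(path))
    values = _parse_column(lines, str(path), 1)[:, 0]
    return TimeSeries(values, rate)


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {_FMT % ts.sampling_rate}\n")
        np.savetxt(fh, ts.samples, fmt=_FMT)


def read_speed(path: str | Path) -> SpeedTrace:
    lines = Path(path).read_text().splitlines()
    rate = _read_rate_header(lines, str(path))
    values = _parse_column(lines, str(path), 1)[:, 0]
    return SpeedTrace(values, rate)


def read_psd(path: str | Path) -> PowerSpectrum:
    lines = Path(path).read_text().splitlines()
    data = _parse_column(lines, str(path), 2)
    return PowerSpectrum(data[:, 0], data[:, 1])


def write_psd(ps: PowerSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: frequency_hz\tlog10_power\n")
        np.savetxt(fh, np.column_stack([ps.freqs, ps.log_power]), fmt=_FMT, delimiter="\t")


# ---------------------------------------------------------------------------
# results


def _params_to_dict(params: AperiodicParams) -> dict[str, Any]:
    out: dict[str, Any] = {
        "offset": params.offset,
        "exponents": list(params.exponents),
    }
    for key in ("knee1", "knee2", "kprime"):
        value = getattr(params, key)
        if value is not None:
            out[key] = value
    if params.s is not None:
        out["s"] = list(params.s)
    if params.kprime is not None and params.effective_knee2 is not None:
        out["effective_knee2"] = params.effective_knee2
    return out


def fit_to_dict(
    fit: AperiodicFit,
    full_model_error: float | None = None,
    config: dict | None = None,
) -> dict[str, Any]:
    out = {
        "model": fit.kind.value,
        "params": _params_to_dict(fit.params),
        "freq_range": list(fit.freq_range),
        "ap_error": fit.ap_error,
        "full_model_error": full_model_error,
        "bic": fit.bic,
        "n_free_params": fit.n_free,
        "canonicalized": fit.canonicalized,
        "version": __version__,
        "config": config or {},
    }
    return out


def fit_from_dict(data: dict[str, Any]) -> AperiodicFit:
    """Rebuild a fit (parameters and scores) from its JSON form.

    The stored curve is re-evaluated on demand, so only parameters travel.
    """
    validate_result(data)
    p = data["params"]
    params = AperiodicParams(
        offset=float(p["offset"]),
        exponents=tuple(p["exponents"]),
        knee1=p.get("knee1"),
        knee2=p.get("knee2"),
        kprime=p.get("kprime"),
        s=tuple(p["s"]) if p.get("s") else None,
    )
    kind = AperiodicModelKind(data["model"])
    lo, hi = data["freq_range"]
    freqs = np.array([lo, hi])
    from .aperiodic import evaluate_model

    return AperiodicFit(
        kind=kind,
        params=params,
        freq_range=(float(lo), float(hi)),
        freqs=freqs,
        curve=evaluate_model(kind, params, freqs),
        ap_error=float(data["ap_error"]),
        bic=float(data["bic"]),
        n_free=int(data.get("n_free_params", 0)),
        canonicalized=bool(data["canonicalized"]),
    )


def validate_result(data: dict[str, Any]) -> None:
    missing = [k for k in RESULT_REQUIRED_KEYS if k not in data]
    if missing:
        raise ValueError(f"result JSON missing required key(s): {missing}")
    if "offset" not in data["params"] or "exponents" not in data["params"]:
        raise ValueError("result JSON params must include offset and exponents")


def write_result(data: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def peaks_to_dict(peaks: Sequence[Peak]) -> list[dict[str, Any]]:
    return [
        {
            "band": p.band,
            "center_freq": p.center_freq,
            "height": p.height,
            "std": p.std,
            "bandwidth": p.bandwidth,
        }
        for p in peaks
    ]


def history_to_dict(result: IterationResult, config: dict | None = None) -> dict[str, Any]:
    return {
        "n_iterations": result.n_iterations,
        "version": __version__,
        "config": config or {},
        "history": [
            {
                "iteration": i,
                "aperiodic": fit_to_dict(step.aperiodic, step.full_model_error),
                "peaks": peaks_to_dict(step.peaks),
                "ap_error": step.ap_error,
                "full_model_error": step.full_model_error,
            }
            for i, step in enumerate(result.steps)
        ],
    }


# ---------------------------------------------------------------------------
# configs


def _peaks_from_cfg(items: Sequence[dict]) -> tuple[SpectralPeakSpec, ...]:
    out = []
    for item in items or ():
        if "bandwidth" in item and "std" not in item:
            item = dict(item)
            item["std"] = item.pop("bandwidth") / 2.0
        out.append(
            SpectralPeakSpec(
                center_freq=float(item["center_freq"]),
                height_db=float(item["height_db"]),
                std=float(item["std"]),
            )
        )
    return tuple(out)


def read_simulation_spec(path: str | Path) -> SimulationSpec:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: simulation config must be a mapping")
    known = {
        "duration", "sampling_rate", "aperiodic_exponent", "power_at_1hz",
        "peaks", "noise_peaks", "base_noise_sigma", "seed",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"{path}: unknown simulation key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {k: cfg[k] for k in known & set(cfg)}
    if "peaks" in kwargs:
        kwargs["peaks"] = _peaks_from_cfg(kwargs["peaks"])
    if "noise_peaks" in kwargs:
        kwargs["noise_peaks"] = _peaks_from_cfg(kwargs["noise_peaks"])
    return SimulationSpec(**kwargs)


def write_simulation_spec(spec: SimulationSpec, path: str | Path) -> None:
    def peak_dicts(peaks):
        return [
            {"center_freq": p.center_freq, "height_db": p.height_db, "std": p.std}
            for p in peaks
        ]

    cfg = {
        "duration": spec.duration,
        "sampling_rate": spec.sampling_rate,
        "aperiodic_exponent": spec.aperiodic_exponent,
        "power_at_1hz": spec.power_at_1hz,
        "peaks": peak_dicts(spec.peaks),
        "noise_peaks": peak_dicts(spec.noise_peaks),
        "base_noise_sigma": spec.base_noise_sigma,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_band_config(path: str | Path) -> tuple[BandConfig, ...]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, list):
        raise ValueError(f"{path}: band config must be a list of bands")
    bands = []
    for item in cfg:
        bands.append(
            BandConfig(
                name=str(item["name"]),
                detection_range=tuple(float(v) for v in item["detection_range"]),
                cf_bounds=tuple(float(v) for v in item["cf_bounds"]),
                peak_width_limits=tuple(float(v) for v in item["peak_width_limits"]),
                peak_threshold=float(item["peak_threshold"]),
                min_peak_height=float(item["min_peak_height"]),
            )
        )
    return tuple(bands)


def write_band_config(bands: Sequence[BandConfig], path: str | Path) -> None:
    cfg = [
        {
            "name": b.name,
            "detection_range": list(b.detection_range),
            "cf_bounds": list(b.cf_bounds),
            "peak_width_limits": list(b.peak_width_limits),
            "peak_threshold": b.peak_threshold,
            "min_peak_height": b.min_peak_height,
        }
        for b in bands
    ]
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
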