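"""The five nested aperiodic models and their fitting machinery.

All models describe log10 power L as a function of frequency f (Hz), with
every logarithm in base 10:

* ``1exp``:        L = b - n log(f)
* ``flat+1exp``:   L = b - log(1 + (f/k)^n)
* ``2exp``:        L = b - log((f/k)^n1 + (f/k)^n2)
* ``2exp+flat``:   L = b - log((f/k)^n1 + (f/k)^n2) + log((f/k)^n2 + k')
* ``3exp``:        L = b - log((f/k)^-s2 + (f/k)^s3) + log((f/k')^-s1 + (f/k')^s2)

``1exp`` is a straight line in log-log axes; ``flat+1exp`` is a Lorentzian
with a flat regime below the knee k; ``2exp`` lets the pre-knee regime have
a nonzero exponent as well.  The two wide-band models add a third regime so
that spectra can be fitted to 400 Hz: ``2exp+flat`` flattens above an
effective second knee (where (f/k)^n2 equals the auxiliary constant k'),
while ``3exp`` lets the final slope -n3 be free, with the exponent mapping
n1 = s1 - s2, n2 = s1 + s3, n3 = s3 - s2.

Wide-band fitting is step-wise: ``2exp`` is fitted on 4-200 Hz first, then
the first exponent, first knee and the value at 4 Hz are frozen while the
remaining high-frequency parameters are refitted on 4-400 Hz.  Freezing
keeps the low-frequency parameters - the biologically interpretable ones -
from being traded away to absorb the high-frequency roll-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize

from .core import PowerSpectrum

__all__ = [
    "AperiodicModelKind",
    "AperiodicParams",
    "AperiodicFit",
    "FitError",
    "evaluate_model",
    "fit_aperiodic",
    "canonicalize_2exp",
    "stepwise_fit_400",
    "aperiodic_fit_error",
    "bic",
    "N_FREE_PARAMS",
]

logger = logging.getLogger(__name__)


class AperiodicModelKind(str, Enum):
    ONE_EXP = "1exp"
    FLAT_ONE_EXP = "flat+1exp"
    TWO_EXP = "2exp"
    TWO_EXP_FLAT = "2exp+flat"
    THREE_EXP = "3exp"


#: Free parameters counted in the BIC penalty.  The wide-band models are
#: fitted step-wise, so only their stage-2 free parameters count (frozen
#: stage-1 values are constants): 2exp+flat frees (n2, k') and 3exp frees
#: (s2, s3, k').
N_FREE_PARAMS = {
    AperiodicModelKind.ONE_EXP: 2,
    AperiodicModelKind.FLAT_ONE_EXP: 3,
    AperiodicModelKind.TWO_EXP: 4,
    AperiodicModelKind.TWO_EXP_FLAT: 2,
    AperiodicModelKind.THREE_EXP: 3,
}


@dataclass(frozen=True)
class AperiodicParams:
    """Parameters of one aperiodic model.

    ``exponents`` holds (n,), (n1, n2) or (n1, n2, n3) depending on the
    model; ``knee1``/``knee2`` are in Hz.  For ``2exp+flat`` the raw
    auxiliary constant k' is kept in ``kprime`` and the effective second
    knee (the frequency where the added term transitions) is exposed as
    :attr:`effective_knee2`.  For ``3exp`` the raw shape parameters
    (s1, s2, s3) are kept in ``s`` alongside the derived exponents.
    """

    offset: float
    exponents: tuple[float, ...]
    knee1: float | None = None
    knee2: float | None = None
    kprime: float | None = None
    s: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", tuple(float(e) for e in self.exponents))
        for knee in (self.knee1, self.knee2):
            if knee is not None and not (knee > 0):
                raise ValueError(f"knee frequencies must be positive, got {knee}")
        if self.s is not None:
            if any(si <= 0 for si in self.s):
                raise ValueError("s1, s2, s3 must all be positive")
            object.__setattr__(self, "s", tuple(float(si) for si in self.s))

    @property
    def effective_knee2(self) -> float | None:
        """For ``2exp+flat``: frequency where (f/k)^n2 = |k'|."""
        if self.kprime is None or self.knee1 is None:
            return None
        n2 = self.exponents[1]
        if n2 <= 0 or self.kprime <= 0:
            return None
        return self.knee1 * self.kprime ** (1.0 / n2)


class FitError(RuntimeError):
    """Raised when every optimizer start fails; carries the best partial fit."""

    def __init__(self, message: str, partial: "AperiodicFit | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class AperiodicFit:
    """One converged aperiodic fit: model, parameters, curve and scores."""

    kind: AperiodicModelKind
    params: AperiodicParams
    freq_range: tuple[float, float]
    freqs: np.ndarray
    curve: np.ndarray
    ap_error: float
    bic: float
    n_free: int
    canonicalized: bool = False
    stage1: "AperiodicFit | None" = field(default=None, repr=False)

    def evaluate(self, freqs: Sequence[float]) -> np.ndarray:
        """Model curve from the stored parameters on an arbitrary grid."""
        return evaluate_model(self.kind, self.params, freqs)


def evaluate_model(
    kind: AperiodicModelKind,
    params: AperiodicParams,
    freqs: Sequence[float],
) -> np.ndarray:
    """Pointwise evaluation of an aperiodic model in log10-power units."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    kind = AperiodicModelKind(kind)
    b = params.offset
    if kind is AperiodicModelKind.ONE_EXP:
        (n,) = params.exponents[:1]
        return b - n * np.log10(f)
    if kind is AperiodicModelKind.FLAT_ONE_EXP:
        if params.knee1 is None:
            raise ValueError("flat+1exp requires knee1")
        (n,) = params.exponents[:1]
        return b - np.log10(1.0 + (f / params.knee1) ** n)
    if kind is AperiodicModelKind.TWO_EXP:
        if params.knee1 is None or len(params.exponents) < 2:
            raise ValueError("2exp requires knee1 and two exponents")
        n1, n2 = params.exponents[:2]
        r = f / params.knee1
        return b - np.log10(r**n1 + r**n2)
    if kind is AperiodicModelKind.TWO_EXP_FLAT:
        if params.knee1 is None or params.kprime is None or len(params.exponents) < 2:
            raise ValueError("2exp+flat requires knee1, kprime and two exponents")
        n1, n2 = params.exponents[:2]
        r = f / params.knee1
        return b - np.log10(r**n1 + r**n2) + np.log10(r**n2 + params.kprime)
    if kind is AperiodicModelKind.THREE_EXP:
        if params.s is None or params.knee1 is None or params.knee2 is None:
            raise ValueError("3exp requires s=(s1,s2,s3), knee1 and knee2")
        s1, s2, s3 = params.s
        r1 = f / params.knee1
        r2 = f / params.knee2
        return b - np.log10(r1**-s2 + r1**s3) + np.log10(r2**-s1 + r2**s2)
    raise ValueError(f"unknown model kind {kind!r}")


def aperiodic_fit_error(
    ps: PowerSpectrum,
    fit: AperiodicFit,
    freq_range: tuple[float, float] | None = None,
) -> float:
    """Mean absolute difference between the spectrum and the aperiodic curve."""
    if freq_range is None:
        freq_range = fit.freq_range
    mask = ps.band_mask(*freq_range)
    if not mask.any():
        raise ValueError(f"no frequency bins inside {freq_range}")
    curve = fit.evaluate(ps.freqs[mask])
    return float(np.mean(np.abs(ps.log_power[mask] - curve)))


def bic(
    ps: PowerSpectrum,
    fit: AperiodicFit,
    n_params: int | None = None,
    freq_range: tuple[float, float] | None = None,
) -> float:
    """Bayesian information criterion, n ln(sigma^2) + k ln(n).

    ``n`` is the number of frequency bins in the range, ``k`` the number of
    free parameters, and sigma^2 the mean squared aperiodic residual.
    """
    if freq_range is None:
        freq_range = fit.freq_range
    mask = ps.band_mask(*freq_range)
    if not mask.any():
        raise ValueError(f"no frequency bins inside {freq_range}")
    resid = ps.log_power[mask] - fit.evaluate(ps.freqs[mask])
    sigma2 = float(np.mean(resid**2))
    if sigma2 == 0.0:
        raise ValueError("degenerate perfect fit: sigma^2 = 0")
    n = int(mask.sum())
    k = fit.n_free if n_params is None else n_params
    return n * math.log(sigma2) + k * math.log(n)


# ---------------------------------------------------------------------------
# fitting


def _pack(kind: AperiodicModelKind, params: AperiodicParams) -> np.ndarray:
    if kind is AperiodicModelKind.ONE_EXP:
        return np.array([params.offset, params.exponents[0]])
    if kind is AperiodicModelKind.FLAT_ONE_EXP:
        return np.array([params.offset, params.exponents[0], params.knee1])
    if kind is AperiodicModelKind.TWO_EXP:
        return np.array([params.offset, *params.exponents[:2], params.knee1])
    raise ValueError(f"free fitting not supported for {kind!r}; use stepwise_fit_400")


def _unpack(kind: AperiodicModelKind, x: np.ndarray) -> AperiodicParams:
    if kind is AperiodicModelKind.ONE_EXP:
        return AperiodicParams(offset=x[0], exponents=(x[1],))
    if kind is AperiodicModelKind.FLAT_ONE_EXP:
        return AperiodicParams(offset=x[0], exponents=(x[1],), knee1=x[2])
    return AperiodicParams(offset=x[0], exponents=(x[1], x[2]), knee1=x[3])


def _piecewise_slopes(logf: np.ndarray, y: np.ndarray, knee: float) -> tuple[float, float]:
    split = np.log10(knee)
    lo = logf <= split
    hi = ~lo
    slope_lo = np.polyfit(logf[lo], y[lo], 1)[0] if lo.sum() >= 3 else 0.0
    slope_hi = np.polyfit(logf[hi], y[hi], 1)[0] if hi.sum() >= 3 else -1.0
    return -slope_lo, -slope_hi


def _starts_for(
    kind: AperiodicModelKind,
    f: np.ndarray,
    y: np.ndarray,
    n_starts: int,
    fmax: float,
) -> list[np.ndarray]:
    logf = np.log10(f)
    knees = np.geomspace(5.0, min(150.0, 0.75 * fmax), n_starts)
    starts = []
    for k in knees:
        n_lo, n_hi = _piecewise_slopes(logf, y, k)
        n_lo = float(np.clip(n_lo, 0.0, 8.0))
        n_hi = float(np.clip(n_hi, 0.05, 8.0))
        y_at_k = float(np.interp(k, f, y))
        if kind is AperiodicModelKind.FLAT_ONE_EXP:
            starts.append(np.array([y_at_k + np.log10(2.0), n_hi, k]))
        else:
            if n_hi <= n_lo:
                n_hi = n_lo + 0.5
            starts.append(np.array([y_at_k + np.log10(2.0), n_lo, n_hi, k]))
    return starts


def fit_aperiodic(
    ps: PowerSpectrum,
    kind: AperiodicModelKind,
    freq_range: tuple[float, float] = (4.0, 200.0),
    n_starts: int = 8,
    extra_starts: Sequence[AperiodicParams] | None = None,
) -> AperiodicFit:
    """Bounded nonlinear least squares of one aperiodic model on log10 power.

    ``1exp`` is linear in log-log axes and is solved in closed form.  The
    knee models run ``n_starts`` optimizer starts with knee candidates
    log-spaced in [5, 150] Hz and exponents seeded from piecewise log-log
    regression slopes; ``extra_starts`` lets callers warm-start from a
    previous solution (e.g. the preceding iteration of the alternating
    procedure, or a poorer nested model).  Ties are broken by the lower mean
    absolute error, then the lower BIC.

    Exponents are bounded to [0, 8] and knees to [4 Hz, upper fit bound].
    """
    kind = AperiodicModelKind(kind)
    sub = ps.restrict(*freq_range)
    f, y = sub.freqs, sub.log_power

    if kind is AperiodicModelKind.ONE_EXP:
        slope, intercept = np.polyfit(np.log10(f), y, 1)
        params = AperiodicParams(offset=float(intercept), exponents=(float(-slope),))
        return _finalize(kind, params, sub, freq_range)

    if kind in (AperiodicModelKind.TWO_EXP_FLAT, AperiodicModelKind.THREE_EXP):
        raise ValueError(
            f"{kind.value} is fitted step-wise over 4-400 Hz; use stepwise_fit_400"
        )

    if kind is AperiodicModelKind.FLAT_ONE_EXP:
        lower = np.array([-np.inf, 0.0, 4.0])
        upper = np.array([np.inf, 8.0, freq_range[1]])
    else:
        lower = np.array([-np.inf, 0.0, 0.0, 4.0])
        upper = np.array([np.inf, 8.0, 8.0, freq_range[1]])

    starts = _starts_for(kind, f, y, n_starts, freq_range[1])
    for p in extra_starts or ():
        try:
            starts.append(np.clip(_pack(kind, p), lower, upper))
        except (ValueError, IndexError, TypeError):
            continue

    def residual(x):
        return evaluate_model(kind, _unpack(kind, x), f) - y

    best: AperiodicFit | None = None
    last_exc: Exception | None = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-9, np.where(np.isfinite(upper), upper - 1e-9, x0))
        try:
            sol = optimize.least_squares(
                residual, x0, bounds=(lower, upper), method="trf", max_nfev=400
            )
        except Exception as exc:  # numerical failure on this start
            last_exc = exc
            continue
        cand = _finalize(kind, _unpack(kind, sol.x), sub, freq_range)
        if best is None or (cand.ap_error, cand.bic) < (best.ap_error, best.bic):
            best = cand
    if best is None:
        raise FitError(
            f"all {len(starts)} optimizer starts failed for {kind.value}: {last_exc}"
        )
    return best


def _finalize(
    kind: AperiodicModelKind,
    params: AperiodicParams,
    sub: PowerSpectrum,
    freq_range: tuple[float, float],
    n_free: int | None = None,
    stage1: AperiodicFit | None = None,
) -> AperiodicFit:
    curve = evaluate_model(kind, params, sub.freqs)
    resid = sub.log_power - curve
    ap_error = float(np.mean(np.abs(resid)))
    sigma2 = float(np.mean(resid**2))
    n = sub.freqs.size
    k = N_FREE_PARAMS[kind] if n_free is None else n_free
    bic_score = n * math.log(sigma2) + k * math.log(n) if sigma2 > 0 else -math.inf
    return AperiodicFit(
        kind=kind,
        params=params,
        freq_range=freq_range,
        freqs=sub.freqs,
        curve=curve,
        ap_error=ap_error,
        bic=bic_score,
        n_free=k,
        stage1=stage1,
    )


def canonicalize_2exp(
    params: AperiodicParams,
    max_knee: float = 195.0,
    min_exponent_gap: float = 0.01,
) -> tuple[AperiodicParams, bool]:
    """Map degenerate ``2exp`` solutions onto the single-exponent form.

    When the two exponents are indistinguishable (|n1 - n2| < 0.01) or the
    knee escapes the fitted range (> 195 Hz), the fit is effectively a
    single power law and the reported knee is meaningless; the parameters
    are then rewritten with n1 = 0, n2 as obtained, and the knee at 4 Hz,
    which is how they are reported for model comparison.  Returns the
    (possibly rewritten) parameters and whether the rule fired.
    """
    n1, n2 = params.exponents[:2]
    if abs(n1 - n2) < min_exponent_gap or (params.knee1 or 0.0) > max_knee:
        return replace(params, exponents=(0.0, n2), knee1=4.0), True
    return params, False


def _stepwise_model_2exp_flat(f, n1, k, n2, kprime, b):
    r = f / k
    return b - np.log10(r**n1 + r**n2) + np.log10(r**n2 + kprime)


def _stepwise_model_3exp(f, k, k2, s1, s2, s3, b):
    r1 = f / k
    r2 = f / k2
    return b - np.log10(r1**-s2 + r1**s3) + np.log10(r2**-s1 + r2**s2)


def stepwise_fit_400(
    ps: PowerSpectrum,
    kind: AperiodicModelKind,
    stage1_range: tuple[float, float] = (4.0, 200.0),
    freq_range: tuple[float, float] = (4.0, 400.0),
    n_starts: int = 8,
) -> AperiodicFit:
    """Two-stage wide-band fit of ``2exp+flat`` or ``3exp`` up to 400 Hz.

    Stage 1 fits ``2exp`` on 4-200 Hz.  Stage 2 then fits the requested
    wide-band model on 4-400 Hz with the first exponent, the first knee and
    the model value at 4 Hz frozen to the stage-1 result; the offset b is
    solved from the 4 Hz constraint at every step, so only the
    high-frequency parameters (n2 and k' for ``2exp+flat``; s2, s3 and the
    second knee for ``3exp``) are free.
    """
    kind = AperiodicModelKind(kind)
    if kind not in (AperiodicModelKind.TWO_EXP_FLAT, AperiodicModelKind.THREE_EXP):
        raise ValueError(f"step-wise fitting applies to 2exp+flat/3exp, not {kind.value}")
    if ps.freqs[-1] < freq_range[1]:
        raise ValueError(
            f"spectrum support ends at {ps.freqs[-1]:.1f} Hz, below {freq_range[1]} Hz"
        )
    stage1 = fit_aperiodic(ps, AperiodicModelKind.TWO_EXP, stage1_range, n_starts)
    n1 = stage1.params.exponents[0]
    k = stage1.params.knee1
    f_anchor = stage1_range[0]
    l_anchor = float(stage1.evaluate(np.array([f_anchor]))[0])

    sub = ps.restrict(*freq_range)
    f, y = sub.freqs, sub.log_power
    n2_s1 = stage1.params.exponents[1]

    if kind is AperiodicModelKind.TWO_EXP_FLAT:
        # x = (n2, log10 k'); b solved so the curve passes through the anchor
        def build(x):
            n2, logkp = x
            kp = 10.0**logkp
            b = l_anchor - _stepwise_model_2exp_flat(f_anchor, n1, k, n2, kp, 0.0)
            return n2, kp, b

        def residual(x):
            n2, kp, b = build(x)
            return _stepwise_model_2exp_flat(f, n1, k, n2, kp, b) - y

        lower = np.array([max(n1 + 1e-3, 0.0), -6.0])
        upper = np.array([8.0, 12.0])
        n2_0 = float(np.clip(n2_s1, lower[0] + 1e-6, 8.0 - 1e-6))
        starts = [
            np.array([n2_0, n2_0 * np.log10(fk / k)])
            for fk in (200.0, 250.0, 300.0, 350.0)
        ]
    else:
        # x = (s2, s3, log10 k2); s1 = n1 + s2 keeps the frozen first exponent
        def build(x):
            s2, s3, logk2 = x
            k2 = 10.0**logk2
            s1 = n1 + s2
            b = l_anchor - _stepwise_model_3exp(f_anchor, k, k2, s1, s2, s3, 0.0)
            return k2, s1, s2, s3, b

        def residual(x):
            k2, s1, s2, s3, b = build(x)
            return _stepwise_model_3exp(f, k, k2, s1, s2, s3, b) - y

        lower = np.array([1e-3, 1e-3, np.log10(max(k, 4.0))])
        upper = np.array([8.0, 8.0, np.log10(2000.0)])
        s3_guess = float(np.clip(n2_s1 - n1 - 0.5, 0.1, 7.5))
        starts = [
            np.array([s2_0, s3_guess, np.log10(fk)])
            for s2_0 in (0.1, 0.5)
            for fk in (250.0, 350.0)
        ]

    best_sol = None
    last_exc: Exception | None = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)
        try:
            sol = optimize.least_squares(
                residual, x0, bounds=(lower, upper), method="trf", max_nfev=600
            )
        except Exception as exc:
            last_exc = exc
            continue
        if best_sol is None or sol.cost < best_sol.cost:
            best_sol = sol
    if best_sol is None:
        raise FitError(f"stage-2 fit failed for {kind.value}: {last_exc}", partial=stage1)

    if kind is AperiodicModelKind.TWO_EXP_FLAT:
        n2, kp, b = build(best_sol.x)
        params = AperiodicParams(
            offset=float(b), exponents=(float(n1), float(n2)), knee1=float(k),
            kprime=float(kp),
        )
    else:
        k2, s1, s2, s3, b = build(best_sol.x)
        params = AperiodicParams(
            offset=float(b),
            exponents=(float(s1 - s2), float(s1 + s3), float(s3 - s2)),
            knee1=float(k),
            knee2=float(k2),
            s=(float(s1), float(s2), float(s3)),
        )
    return _finalize(kind, params, sub, freq_range, stage1=stage1)
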