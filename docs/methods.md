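# Methods

## The problem

Rodent hippocampal local field potentials (LFP) superimpose oscillatory
rhythms — theta (4–12 Hz), slow gamma (19–48 Hz), fast gamma (51–90 Hz),
ripple-band activity (100–200 Hz) — on an aperiodic background whose power
falls roughly as 1/f^n. Estimating either component in isolation biases the
other: narrow-band filtering inherits the 1/f tilt, and an aperiodic fit on
the raw spectrum is pulled upward by the oscillatory bumps, which in turn
distorts the flattened residual that peak fitting consumes. `lfpspec`
separates the two components with a family of nested multi-Lorentzian
aperiodic models, band-restricted Gaussian peak detection, and an
alternating estimation scheme, and ships a synthetic LFP generator that
reproduces the simulation conditions the method is validated on.

All spectra are handled as log10 power spectral density over frequency in
Hz; every logarithm below is base 10.

## Aperiodic models

Five nested forms for the aperiodic log-power L(f):

| model       | form                                                              | free parameters |
|-------------|-------------------------------------------------------------------|-----------------|
| `1exp`      | b − n·log f                                                       | b, n (2)        |
| `flat+1exp` | b − log(1 + (f/k)^n)                                              | b, n, k (3)     |
| `2exp`      | b − log((f/k)^n1 + (f/k)^n2)                                      | b, n1, n2, k (4)|
| `2exp+flat` | b − log((f/k)^n1 + (f/k)^n2) + log((f/k)^n2 + k′)                 | n2, k′ free at stage 2 (2) |
| `3exp`      | b − log((f/k)^−s2 + (f/k)^s3) + log((f/k′)^−s1 + (f/k′)^s2)       | s2, s3, k′ free at stage 2 (3) |

`1exp` is a straight line in log–log axes. `flat+1exp` is a single
Lorentzian: flat below the knee k, slope −n above. `2exp` generalizes the
pre-knee regime to a nonzero exponent n1 (with n2 > n1 past the knee),
which steep two-slope spectra such as dentate-gyrus LFP require. The two
wide-band models add a third regime so spectra can be fitted to 400 Hz,
where acquisition roll-off and a second physiological transition flatten
the spectrum: `2exp+flat` approaches a constant (final slope exactly 0)
past an effective second knee, and `3exp` lets the final slope −n3 be free,
with exponents mapped from the shape parameters as n1 = s1 − s2,
n2 = s1 + s3, n3 = s3 − s2 (s1, s2, s3 > 0, k ≤ k′).

For `2exp+flat` the raw auxiliary constant k′ enters the model inside the
logarithm and is not itself a frequency. We store k′ verbatim and report the
effective second knee at the frequency where (f/k)^n2 = k′, i.e.
f = k·k′^(1/n2) — the point where the added term transitions from constant
to canceling the n2 slope. (An alternative printed reduction, |k′/n2| + k,
is typographically ambiguous; the transition frequency above is the
quantity with a physical reading, so it is what `effective_knee2` exposes.)

### Fitting

Fits are bounded nonlinear least squares on log10 power (`scipy.optimize.
least_squares`, trust-region reflective). `1exp` is linear in log–log axes
and solved in closed form. Knee models run 8 multi-starts with knee
candidates log-spaced in [5, 150] Hz; exponent starts come from piecewise
log–log regression on either side of the candidate knee, and the offset
start matches the data at the knee. Callers can inject extra warm starts
(the alternating procedure passes the previous iteration's solution; the
model-nesting tests seed each richer model from the poorer one's optimum).
Ties are broken by lower mean absolute error, then lower BIC. Bounds:
exponents in [0, 8], knees in [4 Hz, upper fit bound], offset free.

Wide-band fits are step-wise: stage 1 fits `2exp` on 4–200 Hz; stage 2 fits
`2exp+flat` or `3exp` on 4–400 Hz with the first exponent, first knee, and
the curve value at 4 Hz frozen to stage-1 results (the offset is solved
from the 4 Hz constraint at every optimizer step rather than fitted).
Freezing keeps the low-frequency parameters — the ones with biological
readings — from being traded away to absorb the high-frequency roll-off.

### Degenerate `2exp` solutions

When `2exp` collapses onto a single power law, the knee is unidentifiable
and lands anywhere. Two triggers mark this: |n1 − n2| < 0.01, or a reported
knee above 195 Hz (outside the 4–200 Hz fit range). `canonicalize_2exp`
then rewrites the parameters as n1 = 0, n2 as obtained, knee = 4 Hz, and
flags the result. Canonicalization is applied only to *reported*
parameters (CLI `--canonicalize`, final outputs) — never inside the
fitting or iteration loops, whose curves keep the raw solution.

### Error metrics and model comparison

Two errors are tracked over the fitted range: the **aperiodic fit error**,
mean |log10 psd − aperiodic curve|, and the **full model fit error**, mean
|log10 psd − (aperiodic + Σ Gaussians)|. The aperiodic error is the
diagnostic one: the full model error changes little between aperiodic
models because the peaks compensate for background misfit.

Models are compared with BIC = n·ln(σ²) + kₚ·ln(n), where n is the number
of frequency bins, σ² the mean squared aperiodic residual, and kₚ the free
parameter count (2/3/4 for the narrow-band models; 2 and 3 for the
step-wise wide-band models, whose frozen stage-1 values are constants, not
parameters). A bit-exact perfect fit (σ² = 0) raises instead of returning
−∞.

## Periodic peaks

The spectrum is flattened (data minus aperiodic curve, restricted to the
fitted range) and at most one Gaussian h·exp(−(f−cf)²/2σ²) is fitted per
oscillatory band. Per-band settings (detection range, center-frequency
bounds, width limits with bandwidth = 2σ, threshold, minimum height):

| band    | detection (Hz) | cf bounds (Hz) | width limits (Hz) | threshold | min height |
|---------|----------------|----------------|-------------------|-----------|------------|
| theta   | 4–12           | 5, 9.5         | 2, 5              | 1         | 0.10       |
| sgamma  | 19–48          | 25, 40         | 5, 25             | 1         | 0.05       |
| fgamma  | 51–90          | 52, 80         | 3, 35             | 1         | 0.08       |
| ripples | 100–200        | 125, 160       | 10, 30            | 1         | 0.05       |

A candidate is accepted only if the maximum in-band residual exceeds
`threshold` × (SD of the in-band residual, computed on the full band
including the candidate region) and the fitted height reaches the minimum;
cf and width bounds are hard optimizer constraints, so accepted peaks
satisfy them by construction. Gap frequencies between bands (12–19, 48–51,
90–100 Hz) can never carry a peak. Everything starts at 4 Hz — the delta
range is excluded because hippocampal delta is inconsistent during active
behavior. Bands whose detection range has fewer than 8 bins in the
flattened spectrum are skipped quietly, so narrower fit ranges degrade
gracefully. One peak per band (rather than free multi-Gaussian fitting)
prevents a single rhythm from being split across Gaussians; the greedy
whole-spectrum alternative (`mode="highest_gaussian"`) is provided for
comparison only.

## Alternating estimation

`iterate_fit` runs a fixed number of cycles (default 20). Iteration 0 is
the single-pass method: aperiodic fit on the raw spectrum, peaks on the
flattened residual. Every later iteration refits the aperiodic model on the
spectrum with the previous peaks subtracted, then re-detects peaks from
scratch on the new residual (no warm-starting of acceptance decisions, so
there is no hysteresis; the aperiodic optimizer does reuse the previous
solution as one extra start, which changes only speed, not the optimum).
Errors stored in the history are always measured against the raw spectrum.
A fixed iteration count rather than a convergence test keeps runs exactly
reproducible; an optional early stop on stationary aperiodic parameters
(`early_stop_tol`) is off by default. On a noiseless model spectrum the
procedure converges to the injected center frequency to < 0.01%.

## Synthetic LFP generator

Traces are built by spectral shaping: Gaussian white noise is transformed
with a real FFT, each positive-frequency bin is multiplied by
sqrt(target density / white density), the DC bin is zeroed, and the inverse
real FFT (which enforces Hermitian symmetry) returns an exactly real trace.
The target is offset − n·log f with the offset anchored so the 1 Hz value
equals `power_at_1hz`/10 log10 units (heights and offsets quoted in dB are
10·log10 power), plus Gaussian bumps in log10 power for oscillations and
narrow line-noise peaks. Below 1 Hz the target is held at its 1 Hz value;
an unclamped 1/f^n would concentrate most of the trace variance below the
analysis floor. The background can be replaced by any callable returning
log10 power (e.g. a fitted `2exp` model's `evaluate`), which is how the
knee-model parameter-recovery tests inject ground truth.

Standard study conditions: exponent 1.2, 60 dB at 1 Hz, 1 kHz sampling,
600 s duration; theta bumps of ~6 dB relative height (cf 6–9 Hz, bandwidth
2–5 Hz), slow-gamma bumps of ~2 dB (cf 30–40 Hz, bandwidth 5–15 Hz); line
noise of 2.5 dB and 0.5 Hz bandwidth at 50 and 150 Hz. The 600 s default
sits in the middle of typical recording-session lengths and gives Welch
spectra (3 s Hann windows, nfft 4000, 50% overlap → 0.25 Hz spacing,
~400 averaged segments) with per-bin log-power scatter of ~0.02.
`base_noise_sigma` (default 0) can add a white measurement-noise floor; the
shaped trace already carries full spectral-estimation noise, so the floor
is off unless a specific acquisition noise level is being emulated.

What the generator does *not* emulate: non-Gaussian or nonstationary
signals, asymmetric (non-Gaussian) spectral peaks, theta harmonics,
multichannel structure, or movement artifacts. Passing tests therefore
demonstrate correct behavior under the stated spectral model, not
robustness to those violations.

## The simulation benchmark

`lfpspec.benchmark` maps center-frequency estimation error over a cf × bw
grid for four estimators: `bandpass` (zero-phase 4th-order Butterworth
4–12 Hz, then the spectral centroid of the filtered signal's periodogram —
the classic mean-frequency readout), `multitaper` (DPSS spectrogram,
TW = 2, K = 3, 5 s windows, 1 s steps; in-band centroid of the averaged
spectrum, with an argmax mode as an alternative since the conventional
toolbox readout is not pinned down), `single_pass` (iteration 0 of the
parameterization), and `iterative` (iteration 20). The parameterization
estimators run Welch (3 s windows, nfft 4000), subtract the 50/150 Hz noise
peaks, and fit `1exp` over 4–100 Hz — the simulated background is a pure
power law, and a single exponent describes it well to 100 Hz. Per-cell
seeds derive deterministically from (base seed, cell index, initiation
index) via `SeedSequence`, so grids are reproducible bit for bit; cell
parameters are held fixed across initiations and only the noise seed
varies.

**Error convention.** Each cell records |mean over initiations of
100·(cf_est − cf_true)/cf_true| — the magnitude of the mean *signed*
relative error. Averaging signed deviations isolates the estimator's bias,
which is what the grid is meant to map and what iteration removes; taking
absolute values per initiation instead would floor every cell at the
estimator's stochastic scatter (~0.3–1% per initiation at these durations)
regardless of bias, drowning the iterated result. Grid-level summaries are
the mean of the per-cell values. `smooth_grid` offers the display-style 2-D
Gaussian smoothing (std in cell units, reflective boundaries, mass-
conserving) but no summary statistic depends on it.

Default grids are deliberately desk-scale: theta 4 × 4 (cf 6–9 step 1 Hz,
bw 2–5 step 1 Hz) and slow gamma 5 × 5 (cf 30–40, bw 5–15, step 2.5 Hz),
20 initiations per cell — 820 simulated 600 s traces for the full study,
about five minutes on one core. Finer steps reproduce smoother maps but do
not change the grid means materially.

Two known floors limit the iterated theta error at these conditions, both
visible when the pipeline is run on the analytic *expected* Welch spectrum
(target curve convolved with the Hann window kernel): the 3 s window smears
the peak sitting on the steep background, leaving a residual bias of up to
~0.2% at the widest/lowest-frequency cells (duration-independent), and
finite initiations leave ~0.05–0.1% of unaveraged scatter in each cell
mean. On the clean (unconvolved) target curve the iterated error is
numerically zero.

## Numerical choices and edge cases

- Welch uses per-segment constant detrending, so a DC offset changes no
  retained bin; the 0 Hz bin is never stored (log10 power).
- Low-pass + decimation (8th-order Butterworth at 500 Hz, forward-backward,
  integer factor) preserves the spectral shape below 400 Hz to < 0.05
  log10 units; at the critical rate (Nyquist = cutoff) only decimation
  applies. Non-integer decimation factors are rejected.
- Speed masking resamples the camera-rate speed trace by nearest neighbor,
  removes maximal sub-5 cm/s runs of ≥ 450 ms, and returns segments with
  offsets; PSDs of masked data are computed per segment and averaged with
  duration weights (stitching segments would create discontinuity
  artifacts).
- Line-noise removal fits `1exp` + one Gaussian inside center ± 7 Hz
  (43–57 Hz for 50 Hz noise; the same ± 7 Hz window is reused for
  harmonics), subtracts only the Gaussian, and leaves outside bins
  bit-identical. The Gaussian width is capped at 2 Hz so the component
  cannot absorb broadband structure; if the fitted height falls below 0.01
  log10 units the spectrum is returned unchanged with a logged notice.
- Degenerate inputs raise early with explicit messages: non-positive or
  unsorted frequencies, empty fit ranges, windows longer than the trace,
  misaligned speed traces, invalid taper requests (K ≥ 2·TW), σ² = 0 in
  BIC.
- Knee-to-timescale conversion: where a timescale is wanted, use
  τ = 1/(2πk). Reported regional timescales in the literature do not always
  follow this convention, so no result here depends on it.

## Known limitations

- The comparator centroid estimators cannot exceed ~15% grid-mean theta
  error under 6 dB peaks (the band centroid is bounded by the band edges);
  published figures for conventional methods sometimes quote the worst map
  region instead of a grid mean.
- Free (non-step-wise) fitting of the wide-band models is intentionally
  unsupported; the step-wise path is the defined procedure.
- Single-channel only; no time-resolved (spectrogram) parameterization.
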