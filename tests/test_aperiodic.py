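"""Aperiodic models: evaluation, fitting, canonicalization, step-wise fit, BIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpspec import (
    AperiodicModelKind,
    AperiodicParams,
    SimulationSpec,
    aperiodic_fit_error,
    bic,
    canonicalize_2exp,
    evaluate_model,
    fit_aperiodic,
    simulate_time_series,
    stepwise_fit_400,
    welch_psd,
)
from lfpspec.aperiodic import stepwise_fit_400 as stepwise
from lfpspec.core import PowerSpectrum

K = AperiodicModelKind


def _curve(kind, params, grid):
    return PowerSpectrum(grid, evaluate_model(kind, params, grid))


class TestEvaluateModel:
    def test_one_exp_offset_at_1hz(self):
        params = AperiodicParams(offset=5.5, exponents=(2.3,))
        assert evaluate_model(K.ONE_EXP, params, [1.0])[0] == pytest.approx(5.5)

    def test_two_exp_value_at_knee(self):
        # both power-law terms equal 1 at f = k, for any exponents
        for n1, n2 in [(0.5, 3.0), (0.0, 1.0), (2.0, 2.0)]:
            params = AperiodicParams(offset=6.0, exponents=(n1, n2), knee1=50.0)
            value = evaluate_model(K.TWO_EXP, params, [50.0])[0]
            assert value == pytest.approx(6.0 - math.log10(2.0))

    def test_flat_one_exp_equals_two_exp_with_zero_first_exponent(self):
        f = np.geomspace(1.0, 400.0, 200)
        flat = AperiodicParams(offset=6.0, exponents=(2.5,), knee1=30.0)
        two = AperiodicParams(offset=6.0, exponents=(0.0, 2.5), knee1=30.0)
        a = evaluate_model(K.FLAT_ONE_EXP, flat, f)
        b = evaluate_model(K.TWO_EXP, two, f)
        assert np.allclose(a, b)

    def test_three_exp_asymptotic_slopes(self):
        # s1=2, s2=0.5, s3=1.5 -> n1=1.5, n2=3.5, n3=1.0
        k, k2 = 20.0, 2000.0
        params = AperiodicParams(
            offset=6.0, exponents=(1.5, 3.5, 1.0), knee1=k, knee2=k2, s=(2.0, 0.5, 1.5)
        )

        def local_slope(f):
            fa, fb = f * 0.999, f * 1.001
            ya, yb = evaluate_model(K.THREE_EXP, params, [fa, fb])
            return (yb - ya) / (math.log10(fb) - math.log10(fa))

        assert local_slope(0.01 * k) == pytest.approx(-1.5, abs=0.02)
        assert local_slope(math.sqrt(k * k2)) == pytest.approx(-3.5, abs=0.1)
        assert local_slope(100 * k2) == pytest.approx(-1.0, abs=0.02)

    def test_missing_knee_rejected(self):
        with pytest.raises(ValueError, match="knee"):
            evaluate_model(K.TWO_EXP, AperiodicParams(offset=6.0, exponents=(1.0, 2.0)), [10.0])

    @given(
        b=st.floats(-5, 10),
        n1=st.floats(0, 8),
        n2=st.floats(0, 8),
        k=st.floats(4, 200),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_for_nonnegative_exponents(self, b, n1, n2, k):
        f = np.geomspace(1.0, 400.0, 120)
        curves = [
            evaluate_model(K.ONE_EXP, AperiodicParams(b, (n1,)), f),
            evaluate_model(K.FLAT_ONE_EXP, AperiodicParams(b, (n1,), knee1=k), f),
            evaluate_model(K.TWO_EXP, AperiodicParams(b, (n1, n2), knee1=k), f),
        ]
        for curve in curves:
            assert np.all(np.diff(curve) <= 1e-12)


class TestFitAperiodic:
    def test_noiseless_two_exp_round_trip(self, analytic_grid):
        truth = AperiodicParams(offset=6.0, exponents=(0.5, 3.0), knee1=50.0)
        ps = _curve(K.TWO_EXP, truth, analytic_grid)
        fit = fit_aperiodic(ps, K.TWO_EXP, (4.0, 200.0))
        assert fit.params.offset == pytest.approx(6.0, rel=1e-3)
        assert fit.params.exponents[0] == pytest.approx(0.5, rel=1e-3, abs=1e-3)
        assert fit.params.exponents[1] == pytest.approx(3.0, rel=1e-3)
        assert fit.params.knee1 == pytest.approx(50.0, rel=1e-3)

    def test_one_exp_recovers_simulated_exponent(self, peakless_psd):
        fit = fit_aperiodic(peakless_psd, K.ONE_EXP, (4.0, 100.0))
        assert fit.params.exponents[0] == pytest.approx(1.2, abs=0.05)

    def test_two_exp_parameter_recovery_from_simulated_traces(self):
        # ground truth injected through the simulator's arbitrary-curve mode
        truth = AperiodicParams(offset=6.0, exponents=(0.5, 3.0), knee1=50.0)
        background = lambda f: evaluate_model(K.TWO_EXP, truth, f)
        n1s, n2s, knees = [], [], []
        for seed in range(10):
            spec = SimulationSpec(duration=600.0, seed=seed, background=background)
            ps = welch_psd(simulate_time_series(spec), 3.0, 4000)
            fit = fit_aperiodic(ps, K.TWO_EXP, (4.0, 200.0))
            n1s.append(fit.params.exponents[0])
            n2s.append(fit.params.exponents[1])
            knees.append(fit.params.knee1)
        assert np.mean(n1s) == pytest.approx(0.5, abs=0.1)
        assert np.mean(n2s) == pytest.approx(3.0, abs=0.1)
        assert np.mean(knees) == pytest.approx(50.0, rel=0.10)

    def test_stepwise_models_rejected_here(self, peakless_psd):
        with pytest.raises(ValueError, match="step-wise"):
            fit_aperiodic(peakless_psd, K.TWO_EXP_FLAT)


class TestCanonicalize2exp:
    def test_indistinguishable_exponents_trigger(self):
        params = AperiodicParams(offset=6.0, exponents=(1.500, 1.505), knee1=30.0)
        out, fired = canonicalize_2exp(params)
        assert fired
        assert out.exponents == (0.0, 1.505)
        assert out.knee1 == 4.0

    def test_runaway_knee_triggers(self):
        params = AperiodicParams(offset=6.0, exponents=(0.2, 2.0), knee1=200.0)
        out, fired = canonicalize_2exp(params)
        assert fired
        assert out.exponents == (0.0, 2.0)
        assert out.knee1 == 4.0

    def test_well_separated_fit_unchanged(self):
        params = AperiodicParams(offset=6.0, exponents=(0.5, 3.0), knee1=50.0)
        out, fired = canonicalize_2exp(params)
        assert not fired
        assert out == params


@pytest.fixture(scope="module")
def flattening_psd():
    """Analytic spectrum with a second transition to flat above ~300 Hz."""
    grid = np.arange(1.0, 500.01, 0.25)
    truth = AperiodicParams(
        offset=6.0, exponents=(0.3, 2.5), knee1=40.0,
        kprime=(300.0 / 40.0) ** 2.5,
    )
    log_power = evaluate_model(K.TWO_EXP_FLAT, truth, grid)
    rng = np.random.default_rng(11)
    return PowerSpectrum(grid, log_power + 0.01 * rng.standard_normal(grid.size))


class TestStepwiseFit400:
    def test_stage1_parameters_frozen_bit_equal(self, flattening_psd):
        fit = stepwise(flattening_psd, K.TWO_EXP_FLAT)
        assert fit.stage1 is not None
        assert fit.params.exponents[0] == fit.stage1.params.exponents[0]
        assert fit.params.knee1 == fit.stage1.params.knee1

    def test_wideband_model_beats_plain_2exp_to_400(self, flattening_psd):
        wide = stepwise(flattening_psd, K.TWO_EXP_FLAT)
        plain = fit_aperiodic(flattening_psd, K.TWO_EXP, (4.0, 400.0))
        assert wide.ap_error < aperiodic_fit_error(flattening_psd, plain, (4.0, 400.0))

    @pytest.mark.parametrize("kind", [K.TWO_EXP_FLAT, K.THREE_EXP])
    def test_high_frequency_slope_flattens(self, flattening_psd, kind):
        # beyond the second knee the models approach a constant final slope:
        # exactly 0 for 2exp+flat, -n3 (fitted) for 3exp
        fit = stepwise(flattening_psd, kind)
        f = np.array([1.0e5, 1.1e5])
        y = fit.evaluate(f)
        slope = (y[1] - y[0]) / (math.log10(f[1]) - math.log10(f[0]))
        if kind is K.TWO_EXP_FLAT:
            assert abs(slope) < 0.05
        else:
            assert slope == pytest.approx(-fit.params.exponents[2], abs=0.05)
        # and the fitted curve still rolls off between the knees
        mid = fit.evaluate(np.array([100.0, 110.0]))
        mid_slope = (mid[1] - mid[0]) / (math.log10(110.0) - math.log10(100.0))
        assert mid_slope < -1.0

    def test_three_exp_exponent_mapping_consistent(self, flattening_psd):
        fit = stepwise(flattening_psd, K.THREE_EXP)
        s1, s2, s3 = fit.params.s
        n1, n2, n3 = fit.params.exponents
        assert n1 == pytest.approx(s1 - s2)
        assert n2 == pytest.approx(s1 + s3)
        assert n3 == pytest.approx(s3 - s2)
        assert fit.params.knee1 <= fit.params.knee2

    def test_requires_support_to_400(self, peakless_psd):
        truncated = peakless_psd.restrict(1.0, 300.0)
        with pytest.raises(ValueError, match="support"):
            stepwise(truncated, K.TWO_EXP_FLAT)


class TestErrorsAndBic:
    def test_error_zero_for_exact_fit(self, analytic_grid):
        truth = AperiodicParams(offset=6.0, exponents=(1.2,))
        ps = _curve(K.ONE_EXP, truth, analytic_grid)
        fit = fit_aperiodic(ps, K.ONE_EXP, (4.0, 200.0))
        assert aperiodic_fit_error(ps, fit) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_offset_gives_that_error(self, analytic_grid):
        truth = AperiodicParams(offset=6.0, exponents=(1.2,))
        ps = _curve(K.ONE_EXP, truth, analytic_grid)
        fit = fit_aperiodic(ps, K.ONE_EXP, (4.0, 200.0))
        shifted = ps.with_log_power(ps.log_power + 0.2)
        assert aperiodic_fit_error(shifted, fit) == pytest.approx(0.2)

    def test_error_matches_brute_force_loop(self, peakless_psd):
        fit = fit_aperiodic(peakless_psd, K.ONE_EXP, (4.0, 200.0))
        total, count = 0.0, 0
        curve = fit.evaluate(peakless_psd.freqs)
        for f, y, c in zip(peakless_psd.freqs, peakless_psd.log_power, curve):
            if 4.0 <= f <= 200.0:
                total += abs(y - c)
                count += 1
        assert aperiodic_fit_error(peakless_psd, fit) == pytest.approx(total / count)

    def test_empty_range_rejected(self, peakless_psd):
        fit = fit_aperiodic(peakless_psd, K.ONE_EXP, (4.0, 200.0))
        with pytest.raises(ValueError, match="bins"):
            aperiodic_fit_error(peakless_psd, fit, (600.0, 700.0))

    def test_bic_frozen_arithmetic_example(self):
        # n=100, sigma^2=0.01, k=3 -> 100 ln(0.01) + 3 ln(100) = -446.70
        assert 100 * math.log(0.01) + 3 * math.log(100) == pytest.approx(-446.7015, abs=1e-3)
        grid = np.linspace(10.0, 109.0, 100)
        truth = AperiodicParams(offset=6.0, exponents=(1.0,))
        fit = fit_aperiodic(_curve(K.ONE_EXP, truth, grid), K.ONE_EXP, (10.0, 109.0))
        noisy = PowerSpectrum(grid, evaluate_model(K.ONE_EXP, truth, grid) + 0.1)
        # residual is exactly 0.1 everywhere -> sigma^2 = 0.01 over 100 bins
        assert bic(noisy, fit, n_params=3, freq_range=(10.0, 109.0)) == pytest.approx(
            -446.7015, abs=1e-3
        )

    def test_bic_penalty_monotone_in_parameter_count(self, peakless_psd):
        fit = fit_aperiodic(peakless_psd, K.ONE_EXP, (4.0, 200.0))
        values = [bic(peakless_psd, fit, n_params=k) for k in (2, 3, 4)]
        assert values[0] < values[1] < values[2]

    def test_perfect_fit_bic_rejected(self, analytic_grid):
        truth = AperiodicParams(offset=6.0, exponents=(1.2,))
        fit = fit_aperiodic(_curve(K.ONE_EXP, truth, analytic_grid), K.ONE_EXP, (4.0, 200.0))
        # a spectrum bit-identical to the fitted curve has sigma^2 = 0
        exact = PowerSpectrum(analytic_grid, fit.evaluate(analytic_grid))
        with pytest.raises(ValueError, match="degenerate"):
            bic(exact, fit)


@pytest.fixture(scope="module")
def dg_like_psd():
    """Steep two-slope spectrum, like dentate-gyrus LFP (n2 ~ 3.9, knee ~ 70 Hz)."""
    truth = AperiodicParams(offset=6.0, exponents=(0.8, 3.9), knee1=70.0)
    background = lambda f: evaluate_model(K.TWO_EXP, truth, f)
    spec = SimulationSpec(duration=600.0, seed=12, background=background)
    return welch_psd(simulate_time_series(spec), 1.2, 4000)


class TestModelFamilyOrderings:
    def test_nested_models_error_ordering(self, dg_like_psd):
        fit1 = fit_aperiodic(dg_like_psd, K.ONE_EXP, (4.0, 200.0))
        b, n = fit1.params.offset, fit1.params.exponents[0]
        # seed each richer model from the poorer solution (nested forms)
        flat_start = AperiodicParams(
            offset=b - n * math.log10(4.0), exponents=(n,), knee1=4.0
        )
        fit2 = fit_aperiodic(
            dg_like_psd, K.FLAT_ONE_EXP, (4.0, 200.0), extra_starts=[flat_start]
        )
        two_start = AperiodicParams(
            offset=fit2.params.offset, exponents=(0.0, fit2.params.exponents[0]),
            knee1=fit2.params.knee1,
        )
        fit3 = fit_aperiodic(
            dg_like_psd, K.TWO_EXP, (4.0, 200.0), extra_starts=[two_start]
        )
        assert fit3.ap_error <= fit2.ap_error <= fit1.ap_error

    def test_bic_decreases_with_model_complexity_on_steep_spectra(self, dg_like_psd):
        scores = [
            fit_aperiodic(dg_like_psd, kind, (4.0, 200.0)).bic
            for kind in (K.ONE_EXP, K.FLAT_ONE_EXP, K.TWO_EXP)
        ]
        assert scores[0] > scores[1] > scores[2]
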