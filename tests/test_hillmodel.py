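import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsedecode import (
    DoseResponseCurve,
    HillParams,
    build_dose_response,
    fit_hill,
    fit_hill_grid,
    hill_rate,
    normalize_p53_total,
    production_rate,
    recovery_experiment,
    simulate_reporter,
)
from pulsedecode.traces import SingleCellTrace
from tests.conftest import CDKN1A_LIKE, MDM2_LIKE, constant_trace


def _curve_from_params(params, p_values):
    return DoseResponseCurve(
        p53_delayed=np.asarray(p_values, dtype=float),
        rate=hill_rate(np.asarray(p_values, dtype=float), params),
    )


class TestHillRate:
    def test_half_maximal_at_K_and_saturation(self):
        params = HillParams(k_max=100, h=6, K=250)
        assert hill_rate(250.0, params) == pytest.approx(50.0)
        assert hill_rate(0.0, params) == 0.0
        assert hill_rate(1e9, params) == pytest.approx(100.0)

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_p53(self, p_a, p_b):
        params = HillParams(k_max=50, h=7.5, K=400)
        lo, hi = sorted((p_a, p_b))
        assert hill_rate(lo, params) <= hill_rate(hi, params) + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HillParams(k_max=-1, h=2, K=100)
        with pytest.raises(ValueError):
            HillParams(k_max=1, h=0, K=100)
        with pytest.raises(ValueError):
            HillParams(k_max=1, h=2, K=0)

    def test_gamma_unit_conversion(self):
        params = HillParams(k_max=1, h=1, K=1, gamma=6.7e-4)
        assert params.gamma_per_h == pytest.approx(0.0402)


class TestSimulateReporter:
    def test_zero_kmax_is_constant(self, clean_p53_trace):
        out = simulate_reporter(clean_p53_trace, HillParams(0.0, 2, 100, gamma=0.0), 3.0)
        assert np.allclose(out.values, 3.0)

    def test_constant_p53_at_K_grows_at_half_kmax(self):
        """p53 = K with gamma = 0: production sits at k_max/2, so the
        reporter is an exact linear ramp."""
        params = HillParams(k_max=80.0, h=7.5, K=400.0, gamma=0.0)
        p53 = constant_trace(400.0)
        out = simulate_reporter(p53, params)
        expected = params.k_max / 2 * p53.times
        assert np.allclose(out.values, expected, rtol=1e-3)

    def test_no_p53_with_decay_matches_closed_form(self):
        params = HillParams(k_max=50.0, h=4, K=100, gamma=6.7e-4)
        p53 = constant_trace(0.0)
        out = simulate_reporter(p53, params, initial_mcherry=200.0)
        expected = 200.0 * np.exp(-params.gamma_per_h * p53.times)
        assert np.allclose(out.values, expected, rtol=1e-6)

    def test_nondecreasing_without_decay(self, clean_p53_trace):
        params = HillParams(k_max=30, h=5, K=300, gamma=0.0)
        out = simulate_reporter(clean_p53_trace, params)
        assert np.all(np.diff(out.values) >= -1e-9)

    def test_step_halving_convergence(self, clean_p53_trace):
        params = HillParams(k_max=30, h=5, K=300)
        coarse = simulate_reporter(clean_p53_trace, params, substeps=10)
        fine = simulate_reporter(clean_p53_trace, params, substeps=20)
        denom = max(np.abs(fine.values).max(), 1.0)
        assert np.max(np.abs(coarse.values - fine.values)) / denom < 1e-3


class TestProductionRate:
    def test_linear_trace_gives_constant_slope(self):
        t = np.arange(0, 10, 0.5)
        tr = SingleCellTrace("c0", t, 3.0 * t + 1.0)
        assert np.allclose(production_rate(tr), 3.0)

    def test_constant_trace_gives_zero(self):
        assert np.allclose(production_rate(constant_trace(9.0)), 0.0)

    def test_quadratic_exact_at_interior_points(self):
        t = np.arange(0, 5, 0.25)
        tr = SingleCellTrace("c0", t, 2.0 * t**2)
        rate = production_rate(tr)
        assert np.allclose(rate[1:-1], 4.0 * t[1:-1])

    def test_too_short_rejected(self):
        tr = SingleCellTrace("c0", [0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            production_rate(tr)


class TestNormalizeP53:
    def test_identity_and_doubling(self, clean_p53_trace):
        same = normalize_p53_total(clean_p53_trace, 1.0)
        assert np.array_equal(same.values, clean_p53_trace.values)
        doubled = normalize_p53_total(clean_p53_trace, 0.5)
        assert np.allclose(doubled.values, 2.0 * clean_p53_trace.values)

    def test_scaling_linearity(self, clean_p53_trace):
        a = 3.7
        scaled_then = normalize_p53_total(
            clean_p53_trace.copy_with(a * clean_p53_trace.values), 0.4
        )
        then_scaled = normalize_p53_total(clean_p53_trace, 0.4)
        assert np.allclose(scaled_then.values, a * then_scaled.values)

    def test_invalid_fraction_rejected(self, clean_p53_trace):
        with pytest.raises(ValueError):
            normalize_p53_total(clean_p53_trace, 0.0)


class TestDoseResponse:
    def test_points_lie_on_generating_hill_curve(self, fine_longduration_p53):
        params = HillParams(k_max=135, h=7.5, K=407, gamma=0.0, tau_d=2.0)
        mch = simulate_reporter(fine_longduration_p53, params)
        curve = build_dose_response(fine_longduration_p53, mch, tau_d=2.0)
        predicted = hill_rate(curve.p53_delayed, params)
        # within integration + finite-differencing tolerance
        assert np.max(np.abs(curve.rate - predicted)) < 0.02 * params.k_max

    def test_constant_p53_collapses_to_one_abscissa(self):
        p53 = constant_trace(321.0)
        mch = simulate_reporter(p53, HillParams(10, 2, 300, gamma=0.0))
        curve = build_dose_response(p53, mch, tau_d=2.0)
        assert np.allclose(curve.p53_delayed, 321.0)

    def test_zero_delay_pairs_same_frame(self, clean_p53_trace):
        mch = simulate_reporter(clean_p53_trace, HillParams(10, 2, 300, tau_d=0.0))
        curve = build_dose_response(clean_p53_trace, mch, tau_d=0.0)
        mask = (clean_p53_trace.times >= 0) & (clean_p53_trace.times <= 15 + 1e-9)
        assert np.array_equal(curve.p53_delayed, clean_p53_trace.values[mask])

    def test_window_exceeding_span_rejected(self, clean_p53_trace):
        mch = simulate_reporter(clean_p53_trace, HillParams(10, 2, 300))
        with pytest.raises(ValueError):
            build_dose_response(clean_p53_trace, mch, window=(0.0, 30.0))


class TestFitHill:
    def test_exact_points_recovered(self):
        params = HillParams(k_max=135, h=7.5, K=407)
        p = np.geomspace(50, 800, 30)
        fit = fit_hill(_curve_from_params(params, p))
        assert fit.k_max == pytest.approx(135, rel=1e-3)
        assert fit.h == pytest.approx(7.5, rel=1e-3)
        assert fit.K == pytest.approx(407, rel=1e-3)

    def test_degenerate_curve_rejected(self):
        curve = DoseResponseCurve(
            p53_delayed=np.linspace(10, 100, 10), rate=np.full(10, 5.0)
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_hill(curve)

    def test_agrees_with_grid_oracle(self):
        """Multi-start least squares lands in the coarse grid cell the
        brute-force search localized, and beats the lattice loss."""
        params = HillParams(k_max=90.0, h=6.0, K=350.0)
        p = np.geomspace(80, 700, 10)
        curve = _curve_from_params(params, p)
        fit = fit_hill(curve)
        grid, res = fit_hill_grid(curve, n=20, refine=1)
        assert abs(np.log(fit.k_max / grid.k_max)) <= np.log(res["k_ratio_coarse"])
        assert abs(fit.h - grid.h) <= res["dh_coarse"]
        assert abs(np.log(fit.K / grid.K)) <= np.log(res["K_ratio_coarse"])
        fit_loss = float(np.sum((hill_rate(p, fit) - curve.rate) ** 2))
        assert fit_loss <= res["loss"] + 1e-9


class TestRecoveryLoop:
    @pytest.mark.parametrize("params", [MDM2_LIKE, CDKN1A_LIKE], ids=["mdm2", "cdkn1a"])
    def test_noiseless_recovery_within_two_percent(self, params, fine_longduration_p53):
        fit, _ = recovery_experiment(fine_longduration_p53, params)
        assert fit.k_max == pytest.approx(params.k_max, rel=0.02)
        assert fit.h == pytest.approx(params.h, rel=0.02)
        assert fit.K == pytest.approx(params.K, rel=0.02)

    def test_noisy_recovery_within_fifteen_percent(self, fine_longduration_p53):
        fit, _ = recovery_experiment(
            fine_longduration_p53, MDM2_LIKE, noise_frac=0.05, n_points=45, seed=7
        )
        assert fit.k_max == pytest.approx(MDM2_LIKE.k_max, rel=0.15)
        assert fit.h == pytest.approx(MDM2_LIKE.h, rel=0.15)
        assert fit.K == pytest.approx(MDM2_LIKE.K, rel=0.15)
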