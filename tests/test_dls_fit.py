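"""Curve fitting, rate regression, stretch averaging and time series."""

import numpy as np
import pytest

from gwire import (
    CorrelationCurve,
    NoiseSpec,
    OpticalContext,
    RodEnsembleSpec,
    TwoModeParams,
    ValidationError,
    average_stretch,
    default_init,
    diffusion_from_rates,
    fit_curve,
    fit_time_series,
    g2_model,
    make_denaturation_series,
    scattering_vector,
    simulate_monodisperse,
    simulate_rod_ensemble,
)
from gwire.dls_fit import FitResult, RatePoint

from conftest import curve_from_params


class TestDefaultInit:
    def test_jd_from_intercept(self):
        p = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=1.0)
        init = default_init(curve_from_params(p))
        # g2-1 intercept 0.81 -> jd = sqrt(0.81) = 0.9
        assert init.jd == pytest.approx(0.9, rel=0.02)

    def test_tau_from_one_over_e_crossing(self):
        p = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=1.0)
        init = default_init(curve_from_params(p))
        assert 0.5e-3 < init.tau_fast < 2e-3

    def test_flat_curve_rejected(self):
        lag = np.geomspace(1e-6, 1.0, 50)
        curve = CorrelationCurve(lag, np.ones_like(lag), 90.0, OpticalContext())
        with pytest.raises(ValidationError, match="no dynamics"):
            default_init(curve)


class TestFitCurve:
    def test_noiseless_single_exponential_recovery(self):
        truth = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=1.0)
        fit = fit_curve(curve_from_params(truth), seed=0)
        assert fit.converged
        assert fit.n_modes_used == 1
        assert fit.params.tau_fast == pytest.approx(1e-3, rel=1e-6)
        assert fit.params.s_fast == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize(
        "truth",
        [
            TwoModeParams(jd=0.9, a_fast=0.7, tau_fast=0.5e-3, s_fast=0.9,
                          tau_slow=50e-3, s_slow=0.8),
            TwoModeParams(jd=0.8, a_fast=0.6, tau_fast=1e-4, s_fast=1.0,
                          tau_slow=5e-2, s_slow=0.6, y0=0.005),
            TwoModeParams(jd=0.95, a_fast=0.85, tau_fast=2e-3, s_fast=0.75,
                          tau_slow=0.8, s_slow=0.95),
        ],
    )
    def test_noiseless_two_mode_round_trip(self, truth):
        fit = fit_curve(curve_from_params(truth), seed=0)
        assert fit.converged and fit.n_modes_used == 2
        for name in ("jd", "a_fast", "tau_fast", "s_fast", "tau_slow", "s_slow"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-4
            ), name

    def test_polydisperse_decay_gives_stretched_fit(self):
        spec = RodEnsembleSpec("lognormal", {"median": 30e-9, "sigma_log": 0.4})
        ds = simulate_rod_ensemble(spec, 64, angles=[90.0],
                                   noise=NoiseSpec(0, 0, 7))
        fit = fit_curve(ds.curves[0], n_modes=1, seed=0)
        assert fit.converged
        assert fit.params.s_fast < 0.995

    def test_deterministic_given_seed(self):
        ds = simulate_monodisperse(1.0e-10, angles=[90.0],
                                   noise=NoiseSpec(0.01, 0.01, 5))
        a = fit_curve(ds.curves[0], seed=3)
        b = fit_curve(ds.curves[0], seed=3)
        assert a.params == b.params and a.residual_rms == b.residual_rms

    def test_too_few_points_rejected(self):
        p = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=1.0)
        short = curve_from_params(p, n_points=8)
        with pytest.raises(ValidationError):
            fit_curve(short)

    def test_narrow_lag_span_rejected(self):
        lag = np.linspace(1e-3, 2e-3, 50)
        p = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=1.0)
        curve = CorrelationCurve(lag, g2_model(lag, p), 90.0, OpticalContext())
        with pytest.raises(ValidationError, match="decades"):
            fit_curve(curve)


class TestDiffusionFromRates:
    def _points(self, D, angles, noise_frac=0.0, seed=1,
                context=OpticalContext()):
        rng = np.random.default_rng(seed)
        points = []
        for angle in angles:
            q2 = scattering_vector(angle, context) ** 2
            rate = D * q2 * (1 + noise_frac * rng.standard_normal())
            points.append(RatePoint(q_squared=q2, inverse_tau_f=rate,
                                    angle_deg=angle))
        return points

    def test_exact_line(self):
        points = self._points(1.0e-10, [30, 60, 90, 120])
        fit = diffusion_from_rates(points)
        assert fit.D == pytest.approx(1.0e-10, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_rates_recovered_within_three_percent(self):
        points = self._points(0.85e-10, [30, 50, 70, 90, 110, 130],
                              noise_frac=0.01, seed=1)
        fit = diffusion_from_rates(points)
        assert fit.D == pytest.approx(0.85e-10, rel=0.03)

    def test_through_origin_option(self):
        points = self._points(0.5e-10, [40, 80, 120])
        fit = diffusion_from_rates(points, through_origin=True)
        assert fit.through_origin and fit.intercept == 0.0
        assert fit.D == pytest.approx(0.5e-10, rel=1e-12)

    def test_two_points_free_intercept_underdetermined(self):
        points = self._points(1.0e-10, [40, 90])
        with pytest.raises(ValidationError):
            diffusion_from_rates(points, through_origin=False)
        diffusion_from_rates(points, through_origin=True)  # but this is fine

    def test_single_angle_rejected(self):
        q2 = scattering_vector(90, OpticalContext()) ** 2
        points = [RatePoint(q_squared=q2, inverse_tau_f=r, angle_deg=90)
                  for r in (1e3, 1.1e3, 0.9e3)]
        with pytest.raises(ValidationError, match="single-angle"):
            diffusion_from_rates(points)

    def test_permutation_invariant(self):
        points = self._points(0.7e-10, [30, 60, 90, 120], noise_frac=0.02)
        fit_a = diffusion_from_rates(points)
        fit_b = diffusion_from_rates(points[::-1])
        assert fit_a.D == pytest.approx(fit_b.D, rel=1e-14)


def _fit_result(s_fast, converged=True):
    params = TwoModeParams(jd=0.9, a_fast=1.0, tau_fast=1e-3, s_fast=s_fast)
    return FitResult(params=params, residual_rms=0.0, converged=converged,
                     n_modes_used=1)


class TestAverageStretch:
    def test_uniform_stretch(self):
        summary = average_stretch([_fit_result(1.0)] * 4)
        assert summary.s_mean == 1.0 and summary.s_sem == 0.0

    def test_arithmetic_mean(self):
        summary = average_stretch([_fit_result(s) for s in (0.8, 0.9, 1.0)])
        assert summary.s_mean == pytest.approx(0.9)
        assert summary.n_angles == 3

    def test_unconverged_fits_excluded(self):
        fits = [_fit_result(1.0), _fit_result(0.5, converged=False)]
        assert average_stretch(fits).s_mean == 1.0

    def test_no_converged_fits_rejected(self):
        with pytest.raises(ValidationError):
            average_stretch([_fit_result(1.0, converged=False)])

    def test_monodisperse_noiseless_curves_give_unity(self):
        ds = simulate_monodisperse(1.0e-10, angles=[40, 60, 80, 100, 120])
        fits = [fit_curve(c, seed=0) for c in ds.curves]
        assert average_stretch(fits).s_mean == pytest.approx(1.0, abs=1e-3)

    def test_stretch_drops_with_polydispersity_width(self):
        means = {}
        for sigma in (0.1, 0.5):
            spec = RodEnsembleSpec("lognormal",
                                   {"median": 30e-9, "sigma_log": sigma})
            ds = simulate_rod_ensemble(spec, 48, angles=[60, 90, 120],
                                       noise=NoiseSpec(0, 0, 11))
            fits = [fit_curve(c, n_modes=1, seed=0) for c in ds.curves]
            means[sigma] = average_stretch(fits).s_mean
        assert means[0.5] < means[0.1] <= 1.0 + 1e-9


class TestFitTimeSeries:
    def test_denaturation_series_orders_and_recovers(self):
        series = make_denaturation_series(
            [(1.0, 1.6e-10), (6.0, 1.2e-10)],
            angles=[50, 90, 130],
            noise=NoiseSpec(0.005, 0.005, 2),
        )
        table = fit_time_series(
            [(t, ds.curves) for t, ds in series], seed=0
        )
        assert list(table["time"]) == [1.0, 6.0]
        assert table["ok"].all()
        assert table["D"].iloc[0] > table["D"].iloc[1]
        assert table["D"].iloc[0] == pytest.approx(1.6e-10, rel=0.05)
        assert table["D"].iloc[1] == pytest.approx(1.2e-10, rel=0.05)

    def test_empty_series(self):
        table = fit_time_series([])
        assert len(table) == 0

    def test_single_time_point(self):
        ds = simulate_monodisperse(1.0e-10, angles=[60, 90, 120])
        table = fit_time_series([(0.0, ds.curves)], seed=0)
        assert len(table) == 1 and table["ok"].iloc[0]

    def test_failed_point_flagged_not_dropped(self):
        ds = simulate_monodisperse(1.0e-10, angles=[60, 90, 120])
        table = fit_time_series([(0.0, ds.curves[:1]), (1.0, ds.curves)], seed=0)
        assert len(table) == 2
        assert not table["ok"].iloc[0] and table["message"].iloc[0]
        assert table["ok"].iloc[1]
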