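"""Oligomeric flux closed forms, their oracles, and relative metrics."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from secflux.flux import (
    FluxProfile,
    flux_auc,
    flux_closed_form,
    flux_from_derivatives,
    flux_peak,
    flux_profile,
    relative_flux_metrics,
)
from secflux.models import LogisticParams, half_time
from secflux.secondary import LogisticFit


def make_fit(a=0.03, kappa=0.5, c=0.3, **kw):
    p = LogisticParams(a=a, kappa=kappa, c=c)
    return LogisticFit(params=p, t_half=half_time(p), residual_rms=0.0,
                       converged=True, no_aggregation=False, **kw)


def no_agg_fit(**kw):
    return LogisticFit(params=None, t_half=None, residual_rms=0.0,
                       converged=False, no_aggregation=True, **kw)


class TestClosedFormVsDerivativeForm:
    def test_constant_factor_is_two(self, rng):
        """The derivative-assembled flux equals the closed form up to one
        global constant (2) across random parameters (drawn from the fitted
        regime, where the float64 assembly is well conditioned: its round-off
        grows like c*u*eps with u = (a/c)e^{kappa t})."""
        for _ in range(100):
            p = LogisticParams(
                a=float(np.exp(rng.uniform(np.log(5e-3), np.log(0.25)))),
                kappa=float(np.exp(rng.uniform(np.log(0.05), np.log(5.0)))),
                c=float(rng.uniform(0.25, 1.0)),
            )
            t = np.linspace(0, 3 * half_time(p), 200)
            t = t[t >= 0]
            phi7 = flux_from_derivatives(t, p, r_plus=1.3)
            phi8 = flux_closed_form(t, p, r_plus=1.3)
            ratio = phi7 / phi8
            np.testing.assert_allclose(ratio, 2.0, rtol=1e-8)

    def test_positivity(self, rng):
        for _ in range(1000):
            p = LogisticParams(
                a=float(np.exp(rng.uniform(np.log(1e-5), np.log(5.0)))),
                kappa=float(np.exp(rng.uniform(np.log(1e-2), np.log(8.0)))),
                c=float(rng.uniform(0.05, 1.0)),
            )
            t = np.linspace(-5, 60, 40)
            assert np.all(flux_closed_form(t, p, r_plus=1.0) >= 0)

    def test_halving_r_plus_doubles_flux(self, ref_params):
        t = np.linspace(0, 30, 50)
        np.testing.assert_allclose(
            flux_closed_form(t, ref_params, r_plus=0.5),
            2 * flux_closed_form(t, ref_params, r_plus=1.0),
            rtol=1e-12,
        )


class TestPeak:
    def test_peak_time_matches_numeric_argmax(self):
        fit = make_fit()
        t_peak, phi_peak = flux_peak(fit, r_plus=1.0)
        assert t_peak == pytest.approx(2 * np.log(10), rel=1e-12)
        res = minimize_scalar(
            lambda t: -flux_closed_form(t, fit.params, 1.0),
            bounds=(0, 40), method="bounded",
            options={"xatol": 1e-10},
        )
        assert t_peak == pytest.approx(res.x, abs=1e-6)
        assert phi_peak == pytest.approx(-res.fun, rel=1e-10)

    def test_peak_height_conventions(self):
        fit = make_fit(kappa=0.5, c=0.3)
        _, phi_peak = flux_peak(fit, r_plus=2.0)
        assert phi_peak == pytest.approx(0.25 * 0.3 / (8 * 2.0), rel=1e-12)
        profile = flux_profile(fit, r_plus=2.0)
        assert profile.phi_peak_alt == pytest.approx(2 * profile.phi_peak, rel=1e-12)

    def test_peak_at_origin_when_a_equals_c(self):
        fit = make_fit(a=0.3, c=0.3)
        with pytest.warns(UserWarning, match="precedes"):
            t_peak, _ = flux_peak(fit, r_plus=1.0)
        assert t_peak == pytest.approx(0.0, abs=1e-12)

    def test_grid_max_matches_analytic_peak(self):
        profile = flux_profile(make_fit(), r_plus=1.0, n_grid=4000)
        assert profile.phi.max() == pytest.approx(profile.phi_peak, rel=1e-5)
        assert profile.t_grid[np.argmax(profile.phi)] == pytest.approx(
            profile.t_peak, abs=profile.t_grid[1] - profile.t_grid[0]
        )


class TestAuc:
    def test_reference_value_and_quadrature(self):
        fit = make_fit(a=0.03, kappa=0.5, c=0.3)
        auc = flux_auc(fit, r_plus=1.0)
        assert auc == pytest.approx(0.045 / 0.66, rel=1e-12)
        oracle, _ = quad(lambda t: flux_closed_form(t, fit.params, 1.0), 0, 200)
        assert auc == pytest.approx(oracle, rel=1e-8)

    def test_scaling_in_kappa_and_r_plus(self):
        a1 = flux_auc(make_fit(kappa=0.4), r_plus=1.0)
        assert flux_auc(make_fit(kappa=0.8), r_plus=1.0) == pytest.approx(2 * a1, rel=1e-12)
        assert flux_auc(make_fit(kappa=0.4), r_plus=2.0) == pytest.approx(a1 / 2, rel=1e-12)

    def test_small_a_limit(self):
        auc = flux_auc(make_fit(a=1e-9), r_plus=1.0)
        assert auc == pytest.approx(0.5 * 0.3 / 2, rel=1e-6)  # m0*kappa*c/(2 r+)


class TestProfilesAndRelativeMetrics:
    def test_no_aggregation_zero_profile(self):
        profile = flux_profile(no_agg_fit(condition_id="flat"), r_plus=1.0)
        assert profile.no_aggregation
        assert np.all(profile.phi == 0) and profile.auc == 0

    def test_identical_conditions_relative_one(self):
        profiles = [flux_profile(make_fit(condition_id=c, replicate=(e, 0)), 1.0)
                    for c in ("DMSO", "cmpd") for e in (1, 2)]
        table = relative_flux_metrics(profiles, "DMSO")
        np.testing.assert_allclose(table["mean_relative_auc"], 1.0)
        np.testing.assert_allclose(table["mean_relative_peak"], 1.0)

    def test_complete_inhibition_relative_zero(self):
        profiles = [
            flux_profile(make_fit(condition_id="DMSO", replicate=(1, 0)), 1.0),
            flux_profile(no_agg_fit(condition_id="flat", replicate=(1, 0)), 1.0),
        ]
        table = relative_flux_metrics(profiles, "DMSO")
        assert table.loc["flat", "mean_relative_peak"] == 0.0

    def test_relative_metrics_independent_of_shared_prefactor(self):
        """Scaling every profile's r+ by the same factor cancels in ratios
        (and so would the global factor-2 convention)."""
        def tables(r_scale):
            profiles = [
                flux_profile(make_fit(kappa=k, condition_id=c, replicate=(1, 0)),
                             r_plus=1.7 * r_scale)
                for c, k in [("DMSO", 0.5), ("cmpd", 0.4)]
            ]
            return relative_flux_metrics(profiles, "DMSO")
        np.testing.assert_allclose(
            tables(1.0)["mean_relative_peak"], tables(5.0)["mean_relative_peak"], rtol=1e-12
        )
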