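"""Generalized-logistic fitting and the effective fibril-amplification rate."""

import numpy as np
import pandas as pd
import pytest

from secflux.exceptions import DataError, NormalizationError, ParameterError
from secflux.models import LogisticParams, logistic_mass
from secflux.secondary import (
    AmplificationRate,
    GeneralizedLogisticModel,
    LogisticFit,
    amplification_rate,
    fit_secondary,
    fits_from_frame,
    fits_to_frame,
    relative_amplification,
)
from tests.conftest import make_trace


def model_trace(a=0.03, kappa=0.5, c=0.3, t_end=30.0, n=100, **kw):
    t = np.linspace(0.0, t_end, n)
    p = LogisticParams(a=a, kappa=kappa, c=c)
    kw.setdefault("is_normalized", True)
    return make_trace(t, logistic_mass(t, p), **kw)


class TestGeneralizedLogisticModel:
    def test_noiseless_self_consistency(self):
        """Fitting noiseless model output recovers the generating parameters."""
        tr = model_trace()
        fit = fit_secondary(tr)
        assert fit.converged and not fit.no_aggregation
        assert fit.params.a == pytest.approx(0.03, rel=1e-6)
        assert fit.params.kappa == pytest.approx(0.5, rel=1e-6)
        assert fit.t_half == pytest.approx(9.017179, rel=1e-5)

    def test_profiled_scale_recovers_through_affine_distortion(self):
        tr = model_trace()
        distorted = make_trace(tr.time, 0.95 * tr.signal + 0.02, is_normalized=True)
        est = GeneralizedLogisticModel(profile_scale=True).fit(distorted.time, distorted.signal)
        assert est.kappa_ == pytest.approx(0.5, rel=1e-6)
        assert est.scale_ == pytest.approx(0.95, rel=1e-6)

    def test_flat_trace_flags_no_aggregation(self, rng):
        """Complete inhibition: a flat line yields no kinetic parameters."""
        t = np.linspace(0, 30, 100)
        tr = make_trace(t, np.clip(rng.normal(0.0, 0.02, 100), -0.1, 0.5), is_normalized=True)
        fit = fit_secondary(tr)
        assert fit.no_aggregation and not fit.converged
        assert fit.params is None

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError, match="at least 8"):
            GeneralizedLogisticModel().fit(np.arange(5.0), np.zeros(5))

    def test_unnormalized_trace_rejected(self):
        tr = model_trace(is_normalized=False)
        with pytest.raises(ParameterError, match="normalized"):
            fit_secondary(tr)

    def test_predict_matches_truth(self):
        tr = model_trace()
        est = GeneralizedLogisticModel().fit(tr.time, tr.signal)
        np.testing.assert_allclose(est.predict(tr.time), tr.signal, rtol=1e-6, atol=1e-9)

    def test_fit_state_invariant_exactly_one_outcome(self):
        with pytest.raises(ParameterError):
            LogisticFit(params=None, t_half=None, residual_rms=0.0,
                        converged=True, no_aggregation=False)


class TestAmplificationRate:
    def test_closed_form_matches_numeric_oracle(self):
        """dP/dt equals the squared numeric slope at the numerically located t_half."""
        fit = fit_secondary(model_trace(kappa=0.5))
        rate = amplification_rate(fit, k_plus=1.0)
        # oracle: central-difference slope at the numerically located 0.5-crossing
        from scipy.optimize import brentq

        t_half = brentq(lambda t: logistic_mass(t, fit.params) - 0.5, 0, 40, xtol=1e-13)
        h = 1e-5
        slope = (
            logistic_mass(t_half + h, fit.params) - logistic_mass(t_half - h, fit.params)
        ) / (2 * h)
        assert rate.dP_dt == pytest.approx(slope**2 / 4.0, rel=1e-8)
        # closed form [c*kappa*(2^{1/c}-1)*2^{-(c+1)/c}]^2 / (4 k+)
        c, k = 0.3, fit.params.kappa
        closed = (c * k * (2 ** (1 / c) - 1) * 2 ** (-(c + 1) / c)) ** 2 / 4.0
        assert rate.dP_dt == pytest.approx(closed, rel=1e-8)

    def test_doubling_kappa_quadruples_rate(self):
        r1 = amplification_rate(fit_secondary(model_trace(kappa=0.4)))
        r2 = amplification_rate(fit_secondary(model_trace(kappa=0.8, t_end=20)))
        assert r2.dP_dt / r1.dP_dt == pytest.approx(4.0, rel=1e-5)

    def test_no_aggregation_reports_zero_with_flag(self):
        fit = LogisticFit(params=None, t_half=None, residual_rms=0.0,
                          converged=False, no_aggregation=True, condition_id="x")
        rate = amplification_rate(fit)
        assert rate.dP_dt == 0.0 and rate.complete_inhibition

    def test_invalid_k_plus(self):
        fit = fit_secondary(model_trace())
        with pytest.raises(ParameterError):
            amplification_rate(fit, k_plus=0.0)


class TestRelativeAmplification:
    def _rates(self, values, flags=None):
        flags = flags or {}
        out = []
        for cond, vals in values.items():
            for e, v in enumerate(vals, 1):
                out.append(AmplificationRate(
                    dP_dt=v, condition_id=cond, replicate=(e, 0),
                    complete_inhibition=flags.get(cond, False),
                ))
        return out

    def test_identical_conditions_relative_one(self):
        table = relative_amplification(
            self._rates({"DMSO": [2.0, 2.0], "cmpd": [2.0, 2.0]}), "DMSO"
        )
        np.testing.assert_allclose(table["mean_relative"], 1.0)

    def test_control_normalization_and_sem(self):
        table = relative_amplification(
            self._rates({"DMSO": [1.0, 1.0, 1.0], "cmpd": [0.8, 0.9, 1.0]}), "DMSO"
        )
        assert table.loc["cmpd", "mean_relative"] == pytest.approx(0.9)
        assert table.loc["cmpd", "sem"] == pytest.approx(0.1 / np.sqrt(3), rel=1e-9)

    def test_complete_inhibition_relative_zero(self):
        table = relative_amplification(
            self._rates({"DMSO": [1.0, 1.0], "flat": [0.0, 0.0]}, flags={"flat": True}),
            "DMSO",
        )
        assert table.loc["flat", "mean_relative"] == 0.0
        assert table.loc["flat", "complete_inhibition"]

    def test_control_entirely_inhibited_errors(self):
        with pytest.raises(NormalizationError):
            relative_amplification(
                self._rates({"DMSO": [0.0], "cmpd": [1.0]}, flags={"DMSO": True}), "DMSO"
            )

    def test_k_plus_cancels_in_relative_rates(self):
        """Relative amplification is independent of the shared k+ value."""
        fits = [fit_secondary(model_trace(kappa=k, condition_id=c, replicate=(1, 0)))
                for c, k in [("DMSO", 0.5), ("cmpd", 0.4)]]
        tables = []
        for k_plus in (1.0, 2.7):
            rates = [amplification_rate(f, k_plus=k_plus) for f in fits]
            tables.append(relative_amplification(rates, "DMSO"))
        np.testing.assert_allclose(
            tables[0]["mean_relative"], tables[1]["mean_relative"], rtol=1e-12
        )


def test_fits_frame_round_trip():
    fits = [
        fit_secondary(model_trace(condition_id="DMSO", replicate=(1, 0))),
        LogisticFit(params=None, t_half=None, residual_rms=0.0, converged=False,
                    no_aggregation=True, condition_id="flat", compound_dose=0.25,
                    replicate=(1, 0)),
    ]
    df = fits_to_frame(fits)
    back = fits_from_frame(df)
    assert back[0].params.kappa == pytest.approx(fits[0].params.kappa)
    assert back[1].no_aggregation and back[1].params is None
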