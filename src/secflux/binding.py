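"""Supernatant-depletion binding analysis and constrained 4-parameter
dose-response fitting.

Compound bound to pelleted fibrils is inferred by depletion: bound = total
minus the free compound remaining in the supernatant after ultracentrifugation.
The bound concentration versus ligand concentration is fitted with the
standard four-parameter logistic (4PL) dose-response curve

    R([L]) = R_min + [L]**H * (R_max - R_min) / ([L]**H + Kd_app**H),

optionally with R_max constrained to the receptor (preformed fibril)
concentration assayed.  At [L] = Kd_app the curve passes through
(R_min + R_max)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DataError, NonIdentifiableError, ParameterError

__all__ = [
    "DoseResponseModel",
    "DoseResponseFit",
    "BoundResult",
    "bound_from_supernatant",
    "fit_dose_response",
    "four_param_logistic",
]


@dataclass
class BoundResult:
    """Bound-compound concentrations with clamping diagnostics."""

    bound: np.ndarray
    clamped: np.ndarray  # bool mask of doses clamped to zero


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with the data they were fitted to."""

    r_min: float
    r_max: float
    hill: float
    kd_app: float
    ligand_conc: np.ndarray
    response: np.ndarray
    constrained: bool
    residual_rms: float

    def __post_init__(self) -> None:
        if not (self.kd_app > 0):
            raise ParameterError(f"Kd_app must be > 0, got {self.kd_app}")
        if self.r_max < self.r_min:
            raise ParameterError("R_max must be >= R_min")


def four_param_logistic(ligand, r_min: float, r_max: float, hill: float, kd: float):
    """Evaluate the 4PL curve; monotone in [L] for H > 0, R(0) = R_min."""
    L = np.asarray(ligand, dtype=float)
    Lh = np.power(L, hill, where=L > 0, out=np.zeros_like(L, dtype=float))
    return r_min + Lh * (r_max - r_min) / (Lh + kd**hill)


def bound_from_supernatant(total, supernatant, tolerance: float = 0.05) -> BoundResult:
    """bound = max(total - supernatant, 0) per dose, muM.

    Supernatant exceeding total by more than ``tolerance`` (fractional,
    default 5%) triggers a warning; all negative differences are clamped to
    zero and flagged in the returned mask.
    """
    total = np.asarray(total, dtype=float)
    supernatant = np.asarray(supernatant, dtype=float)
    if total.shape != supernatant.shape:
        raise DataError("total and supernatant must have the same length")
    if np.any(total < 0) or np.any(supernatant < 0):
        raise ParameterError("concentrations must be >= 0")
    diff = total - supernatant
    excess = supernatant > total * (1.0 + tolerance)
    if np.any(excess):
        warnings.warn(
            f"supernatant exceeds total by more than {tolerance:.0%} at dose "
            f"indices {np.flatnonzero(excess).tolist()}; clamping to zero bound",
            stacklevel=2,
        )
    clamped = diff < 0
    return BoundResult(bound=np.maximum(diff, 0.0), clamped=clamped)


class DoseResponseModel(RegressorMixin, BaseEstimator):
    """4PL dose-response fit, optionally with R_max constrained.

    ``fit(L, R)`` estimates (R_min, R_max, H, Kd_app) by least squares; pass
    ``r_max=<receptor concentration>`` to fix the maximum response (e.g. 10
    muM preformed fibrils).  Kd is parameterized in log space (always
    positive); the Hill slope starts at 1 and Kd at the geometric mean of the
    ligand range.  ``predict(L)`` evaluates the fitted curve.

    ``weighting='relative'`` (default) divides residuals by the model value,
    the correct weighting for concentration measurements with a constant
    coefficient of variation (e.g. LC-MS supernatant quantification);
    ``'absolute'`` gives the unweighted fit.  ``r_min_lower`` bounds the
    minimum response from below (0 by default — a bound concentration cannot
    be negative); pass ``None`` to free it.

    Attributes: ``r_min_``, ``r_max_``, ``hill_``, ``kd_``, ``constrained_``,
    ``residual_rms_``.
    """

    def __init__(
        self,
        r_max: float | None = None,
        hill_bounds: tuple[float, float] = (0.05, 20.0),
        weighting: str = "relative",
        r_min_lower: float | None = 0.0,
        tol: float = 1e-12,
    ) -> None:
        self.r_max = r_max
        self.hill_bounds = hill_bounds
        self.weighting = weighting
        self.r_min_lower = r_min_lower
        self.tol = tol

    def fit(self, ligand, response) -> "DoseResponseModel":
        L = np.asarray(ligand, dtype=float).ravel()
        R = np.asarray(response, dtype=float).ravel()
        if L.size != R.size:
            raise DataError("ligand and response must have the same length")
        constrained = self.r_max is not None
        min_doses = 3 if constrained else 4
        if np.unique(L).size < min_doses:
            raise DataError(
                f"need >= {min_doses} distinct ligand concentrations, got {np.unique(L).size}"
            )
        if np.any(L < 0):
            raise ParameterError("ligand concentrations must be >= 0")
        span = float(np.ptp(R))
        if span <= 1e-9 * max(1.0, float(np.max(np.abs(R)))):
            raise NonIdentifiableError(
                "response shows no transition (flat); Kd and H are not identifiable"
            )

        if self.weighting not in ("relative", "absolute"):
            raise ParameterError(
                f"weighting must be 'relative' or 'absolute', got {self.weighting!r}"
            )
        Lpos = L[L > 0]
        kd0 = float(np.sqrt(Lpos.min() * Lpos.max()))
        log_kd_bounds = (np.log(Lpos.min() / 1e3), np.log(Lpos.max() * 1e3))
        r_lo, r_hi = float(R.min()), float(R.max())
        pad = 2.0 * span
        rmin_lo = self.r_min_lower if self.r_min_lower is not None else r_lo - pad
        floor = 1e-3 * span  # weighting floor: avoid dividing by ~0 responses

        def weigh(raw, model):
            if self.weighting == "relative":
                return raw / np.maximum(np.abs(model), floor)
            return raw

        if constrained:
            # params: (r_min, log_kd, hill)
            x0 = np.array([max(r_lo, rmin_lo), np.log(kd0), 1.0])
            lo = np.array([rmin_lo, log_kd_bounds[0], self.hill_bounds[0]])
            hi = np.array([float(self.r_max), log_kd_bounds[1], self.hill_bounds[1]])

            def resid(x):
                m = four_param_logistic(L, x[0], self.r_max, x[2], np.exp(x[1]))
                return weigh(m - R, m)

        else:
            # params: (r_min, r_max, log_kd, hill)
            x0 = np.array([max(r_lo, rmin_lo), r_hi, np.log(kd0), 1.0])
            lo = np.array([rmin_lo, r_lo, log_kd_bounds[0], self.hill_bounds[0]])
            hi = np.array([r_hi, r_hi + pad, log_kd_bounds[1], self.hill_bounds[1]])

            def resid(x):
                m = four_param_logistic(L, x[0], x[1], x[3], np.exp(x[2]))
                return weigh(m - R, m)

        sol = least_squares(
            resid,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
        )
        if constrained:
            self.r_min_, self.r_max_ = float(sol.x[0]), float(self.r_max)
            self.kd_ = float(np.exp(sol.x[1]))
            self.hill_ = float(sol.x[2])
        else:
            self.r_min_, self.r_max_ = float(sol.x[0]), float(sol.x[1])
            self.kd_ = float(np.exp(sol.x[2]))
            self.hill_ = float(sol.x[3])
        self.constrained_ = constrained
        self.residual_rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        self.ligand_ = L
        self.response_ = R
        return self

    def predict(self, ligand):
        return four_param_logistic(ligand, self.r_min_, self.r_max_, self.hill_, self.kd_)

    def to_result(self) -> DoseResponseFit:
        return DoseResponseFit(
            r_min=self.r_min_,
            r_max=self.r_max_,
            hill=self.hill_,
            kd_app=self.kd_,
            ligand_conc=self.ligand_,
            response=self.response_,
            constrained=self.constrained_,
            residual_rms=self.residual_rms_,
        )


def fit_dose_response(
    ligand, response, r_max_constraint: float | None = None
) -> DoseResponseFit:
    """Fit the 4PL curve; ``r_max_constraint`` fixes the maximum response."""
    return DoseResponseModel(r_max=r_max_constraint).fit(ligand, response).to_result()
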