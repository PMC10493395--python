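"""Early-time fitting of lipid-induced (DMPS vesicle) aggregation.

While heterogeneous primary nucleation on the vesicle surface dominates, the
fibril mass grows quadratically,

    M(t) = C * t**2,      C = KM * kn * k_plus * m0**(n+1) * b / (2 * (KM + m0)),

with the Michaelis constant KM (saturation of elongation, fixed at 125 muM),
nucleation reaction order n (fixed at 2), lipid-bound monomer concentration
b = [DMPS]/L (fixed at 3.3 muM) and initial monomer m0.  Only the lumped
prefactor C is identifiable from a single trace; the implied kn*k_plus product
is bookkeeping under the fixed-constant grouping above and cancels in every
control-relative output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import basinhopping
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ParameterError, WindowError
from .relative import build_value_frame, relative_table
from .traces import KineticTrace

__all__ = [
    "EarlyQuadraticModel",
    "LipidFit",
    "fit_lipid_early",
    "relative_lipid_rate",
    "DEFAULT_LIPID_CONSTANTS",
]

#: literature-fixed constants of the one-step heterogeneous nucleation model
DEFAULT_LIPID_CONSTANTS: dict[str, float] = {"KM": 125.0, "n": 2, "b": 3.3, "m0": 20.0}


@dataclass
class LipidFit:
    """Quadratic early-time fit of one lipid-induced trace."""

    prefactor_C: float
    knk_product: float
    KM: float
    n: int
    b: float
    m0: float
    window: tuple[int, int]
    non_physical: bool = False
    no_growth: bool = False
    condition_id: str = ""
    compound_dose: float = 0.0
    replicate: tuple[int, int] = (1, 1)
    relative_value: float | None = field(default=None, compare=False)


def knk_from_prefactor(C: float, KM: float, n: int, b: float, m0: float) -> float:
    """Invert the fixed-constant grouping: kn*k_plus implied by the t^2 prefactor."""
    return C * 2.0 * (KM + m0) / (KM * m0 ** (n + 1) * b)


class EarlyQuadraticModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of M(t) = C*t**2 on the early window of a trace.

    The window is the largest prefix with signal below ``window_fraction`` of
    the plateau (mean of the last ``plateau_window`` points).  The problem is
    linear in C and solved exactly (``method='direct'``); a basin-hopping
    restart route (``method='basinhopping'``) is provided and agrees on this
    convex problem.

    ``fit_intercept`` (default True) adds a nuisance constant to the model;
    it absorbs residual baseline offset left over from normalization (the
    baseline is estimated from a few early points, and without an intercept
    its noise propagates straight into C).  The reported prefactor is always
    the coefficient of t**2; on noiseless data through the origin both
    settings return C exactly.

    Attributes: ``prefactor_C_``, ``knk_product_``, ``window_``.
    """

    def __init__(
        self,
        KM: float = 125.0,
        n: int = 2,
        b: float = 3.3,
        m0: float = 20.0,
        window_fraction: float = 0.3,
        plateau_window: int = 5,
        min_points: int = 3,
        method: str = "direct",
        fit_intercept: bool = True,
        random_state: int = 0,
    ) -> None:
        self.KM = KM
        self.n = n
        self.b = b
        self.m0 = m0
        self.window_fraction = window_fraction
        self.plateau_window = plateau_window
        self.min_points = min_points
        self.method = method
        self.fit_intercept = fit_intercept
        self.random_state = random_state

    def _window(self, t: np.ndarray, y: np.ndarray) -> tuple[int, int]:
        plateau = float(y[-self.plateau_window :].mean())
        above = y > self.window_fraction * plateau + 1e-12
        end = int(np.argmax(above)) if above.any() else y.size
        if end < self.min_points:
            raise WindowError(
                f"only {end} early-time points below {self.window_fraction:g} of "
                f"plateau; need >= {self.min_points}"
            )
        return (0, end)

    def fit(self, t, y, window: tuple[int, int] | None = None) -> "EarlyQuadraticModel":
        for name in ("KM", "b", "m0"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (int(self.n) == self.n and self.n > 0):
            raise ParameterError(f"n must be a positive integer, got {self.n}")
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if window is None:
            window = self._window(t, y)
        lo, hi = window
        tw, yw = t[lo:hi], y[lo:hi]
        t4 = float(np.sum(tw**4))
        if t4 <= 0:
            raise WindowError("window contains no positive times; C is undetermined")
        design = [tw**2]
        if self.fit_intercept:
            design.append(np.ones_like(tw))
        A = np.vstack(design).T
        if self.method == "direct":
            coef, *_ = np.linalg.lstsq(A, yw, rcond=None)
        elif self.method == "basinhopping":
            norms = np.linalg.norm(A, axis=0)
            As = A / norms  # unit-norm columns keep the search well scaled

            def sse(z):
                return float(np.sum((yw - As @ z) ** 2))

            z0 = np.full(A.shape[1], float(np.sum(yw * tw**2) / t4) * 1.5 + 1e-6) * norms
            res = basinhopping(
                sse,
                x0=z0,
                niter=10,
                seed=self.random_state,
                minimizer_kwargs={"method": "BFGS", "options": {"gtol": 1e-12}},
            )
            coef = res.x / norms
        else:
            raise ParameterError(f"method must be 'direct' or 'basinhopping', got {self.method!r}")
        C = float(coef[0])
        self.prefactor_C_ = C
        self.intercept_ = float(coef[1]) if self.fit_intercept else 0.0
        self.knk_product_ = knk_from_prefactor(C, self.KM, self.n, self.b, self.m0)
        self.window_ = (int(lo), int(hi))
        return self

    def predict(self, t):
        return self.prefactor_C_ * np.asarray(t, dtype=float).ravel() ** 2 + self.intercept_


def fit_lipid_early(
    trace: KineticTrace,
    constants: Mapping[str, float] | None = None,
    window_fraction: float = 0.3,
    **kwargs,
) -> LipidFit:
    """Fit the t^2 law to one normalized lipid-induced trace."""
    const = dict(DEFAULT_LIPID_CONSTANTS)
    if constants:
        const.update(constants)
    est = EarlyQuadraticModel(
        KM=const["KM"],
        n=const["n"],
        b=const["b"],
        m0=const["m0"],
        window_fraction=window_fraction,
        **kwargs,
    ).fit(trace.time, trace.signal)
    return LipidFit(
        prefactor_C=est.prefactor_C_,
        knk_product=est.knk_product_,
        KM=const["KM"],
        n=int(const["n"]),
        b=const["b"],
        m0=const["m0"],
        window=est.window_,
        non_physical=not (est.prefactor_C_ > 0),
        no_growth=False,
        condition_id=trace.condition_id,
        compound_dose=trace.compound_dose,
        replicate=trace.replicate,
    )


def no_growth_lipid(trace_like, constants: Mapping[str, float] | None = None) -> LipidFit:
    """Zero-rate placeholder for a flat (fully inhibited) lipid trace."""
    const = dict(DEFAULT_LIPID_CONSTANTS)
    if constants:
        const.update(constants)
    return LipidFit(
        prefactor_C=0.0,
        knk_product=0.0,
        KM=const["KM"],
        n=int(const["n"]),
        b=const["b"],
        m0=const["m0"],
        window=(0, 0),
        no_growth=True,
        condition_id=trace_like.condition_id,
        compound_dose=trace_like.compound_dose,
        replicate=trace_like.replicate,
    )


def relative_lipid_rate(fits: Iterable[LipidFit], control: str):
    """Per-condition mean relative kn*k_plus (== relative C) + SEM versus control."""
    fits = list(fits)
    values = build_value_frame(
        {
            "condition_id": f.condition_id,
            "compound_dose": f.compound_dose,
            "experiment": f.replicate[0],
            "value": 0.0 if f.no_growth else f.knk_product,
            "complete_inhibition": f.no_growth,
        }
        for f in fits
    )
    table = relative_table(values, control)
    ctrl_mean = values.loc[
        (values["condition_id"] == control) & ~values["complete_inhibition"], "value"
    ].mean()
    for f in fits:
        f.relative_value = float((0.0 if f.no_growth else f.knk_product) / ctrl_mean)
    return table
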