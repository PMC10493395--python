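"""Reactive flux toward oligomeric species.

Secondary nucleation on fibril surfaces is a source of new oligomers while
elongation consumes them into mature fibrils; the net flux phi(t) toward
oligomeric species follows from the generalized-logistic description of the
aggregate mass and an effective elongation rate r_plus.  The canonical closed
form used here is

    phi(t) = a * kappa**2 * e^{kappa t} / (2 * r_plus * (1 + (a/c) e^{kappa t})**2)

with exact companions: AUC from t=0, A = m0*kappa*c**2 / (2*r_plus*(a+c));
peak time t_peak = (1/kappa) ln(c/a); peak height m0*kappa**2*c / (8*r_plus).

The derivative-assembled form

    (1/r_plus) * [ (m0/m) * M'' + (m0/m)**2 * (M')**2 ]

collapses algebraically to exactly twice the canonical closed form (the
factor-2 discrepancy between the two printed conventions); both peak-height
conventions are therefore reported, and every control-relative output is
independent of the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .models import LogisticParams, logistic_derivatives, monomer_mass
from .relative import build_value_frame, relative_table
from .secondary import LogisticFit

__all__ = [
    "FluxProfile",
    "flux_closed_form",
    "flux_from_derivatives",
    "flux_profile",
    "flux_peak",
    "flux_auc",
    "relative_flux_metrics",
]


@dataclass
class FluxProfile:
    """Oligomeric flux phi(t) on a time grid with its summary metrics.

    ``phi_peak`` uses the canonical closed form (m0*kappa^2*c/(8 r_plus));
    ``phi_peak_alt`` reports the alternative convention without the factor 2
    (m0*kappa^2*c/(4 r_plus)) for transparency.  Relative metrics are
    independent of the convention.
    """

    t_grid: np.ndarray
    phi: np.ndarray
    r_plus: float
    t_peak: float
    phi_peak: float
    phi_peak_alt: float
    auc: float
    m0: float = 1.0
    no_aggregation: bool = False
    condition_id: str = ""
    compound_dose: float = 0.0
    replicate: tuple[int, int] = (1, 1)
    relative_auc: float | None = field(default=None, compare=False)
    relative_peak: float | None = field(default=None, compare=False)


def flux_closed_form(t, p: LogisticParams, r_plus: float, m0: float = 1.0):
    """Canonical phi(t); numerically stable for large kappa*t."""
    if not (r_plus > 0):
        raise ParameterError(f"r_plus must be > 0, got {r_plus}")
    t = np.asarray(t, dtype=float)
    z = np.log(p.a / p.c) + p.kappa * t
    log_phi = (
        np.log(m0 * p.a * p.kappa**2 / (2.0 * r_plus))
        + p.kappa * t
        - 2.0 * np.logaddexp(0.0, z)
    )
    return np.exp(log_phi)


def flux_from_derivatives(t, p: LogisticParams, r_plus: float, m0: float = 1.0):
    """phi assembled from the analytic derivatives of the logistic curve.

    Equals ``2 * flux_closed_form`` identically (documented factor-2
    difference between the two conventions).
    """
    if not (r_plus > 0):
        raise ParameterError(f"r_plus must be > 0, got {r_plus}")
    d1, d2 = logistic_derivatives(t, p)
    m = monomer_mass(t, p)
    ratio = m0 / m
    return (ratio * d2 + (ratio * d1) ** 2) / r_plus


def _require_converged(fit: LogisticFit) -> LogisticParams:
    if fit.params is None or not fit.converged:
        raise ParameterError(
            f"flux requires a converged fit for {fit.condition_id!r} {fit.replicate}"
        )
    return fit.params


def flux_peak(fit: LogisticFit, r_plus: float, m0: float = 1.0) -> tuple[float, float]:
    """Peak time and canonical peak height of phi.

    t_peak = (1/kappa) ln(c/a); for a >= c the peak falls at or before t = 0
    (warned, value still returned).  Peak height = m0*kappa^2*c/(8*r_plus).
    """
    p = _require_converged(fit)
    if not (r_plus > 0):
        raise ParameterError(f"r_plus must be > 0, got {r_plus}")
    t_peak = float(np.log(p.c / p.a) / p.kappa)
    if p.a >= p.c:
        warnings.warn(
            f"a={p.a:g} >= c={p.c:g}: flux peak at t={t_peak:g} h precedes the "
            "observation window",
            stacklevel=2,
        )
    phi_peak = m0 * p.kappa**2 * p.c / (8.0 * r_plus)
    return t_peak, float(phi_peak)


def flux_auc(fit: LogisticFit, r_plus: float, m0: float = 1.0) -> float:
    """Exact integral of the canonical phi from t=0: m0*kappa*c^2/(2*r_plus*(a+c))."""
    p = _require_converged(fit)
    if not (r_plus > 0):
        raise ParameterError(f"r_plus must be > 0, got {r_plus}")
    return float(m0 * p.kappa * p.c**2 / (2.0 * r_plus * (p.a + p.c)))


def flux_profile(
    fit: LogisticFit,
    r_plus: float,
    t_grid: np.ndarray | None = None,
    n_grid: int = 600,
    m0: float = 1.0,
) -> FluxProfile:
    """Evaluate phi on a grid (default 600 points on [0, 4*t_half]).

    A ``no_aggregation`` fit yields an all-zero profile with the flag set
    (zero relative flux by the complete-inhibition convention).
    """
    if fit.no_aggregation:
        grid = np.asarray(t_grid, dtype=float) if t_grid is not None else np.linspace(0, 1, n_grid)
        return FluxProfile(
            t_grid=grid,
            phi=np.zeros_like(grid),
            r_plus=r_plus,
            t_peak=np.nan,
            phi_peak=0.0,
            phi_peak_alt=0.0,
            auc=0.0,
            m0=m0,
            no_aggregation=True,
            condition_id=fit.condition_id,
            compound_dose=fit.compound_dose,
            replicate=fit.replicate,
        )
    p = _require_converged(fit)
    if t_grid is None:
        t_half = fit.t_half if fit.t_half is not None else 1.0
        t_grid = np.linspace(0.0, 4.0 * t_half, n_grid)
    t_grid = np.asarray(t_grid, dtype=float)
    phi = flux_closed_form(t_grid, p, r_plus, m0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_peak, phi_peak = flux_peak(fit, r_plus, m0)
    return FluxProfile(
        t_grid=t_grid,
        phi=phi,
        r_plus=r_plus,
        t_peak=t_peak,
        phi_peak=phi_peak,
        phi_peak_alt=2.0 * phi_peak,
        auc=flux_auc(fit, r_plus, m0),
        m0=m0,
        no_aggregation=False,
        condition_id=fit.condition_id,
        compound_dose=fit.compound_dose,
        replicate=fit.replicate,
    )


def relative_flux_metrics(profiles: Iterable[FluxProfile], control: str) -> pd.DataFrame:
    """Per-condition relative flux AUC and peak height + SEM versus the control.

    Both metrics are invariant to the global factor-2 convention and to the
    absolute units of r_plus (they cancel in the ratio when shared).
    """
    profiles = list(profiles)

    def _table(attr: str) -> pd.DataFrame:
        values = build_value_frame(
            {
                "condition_id": pr.condition_id,
                "compound_dose": pr.compound_dose,
                "experiment": pr.replicate[0],
                "value": getattr(pr, attr),
                "complete_inhibition": pr.no_aggregation,
            }
            for pr in profiles
        )
        return relative_table(values, control)

    auc = _table("auc").rename(columns={"mean_relative": "mean_relative_auc", "sem": "sem_auc"})
    peak = _table("phi_peak").rename(
        columns={"mean_relative": "mean_relative_peak", "sem": "sem_peak"}
    )
    out = auc.join(peak[["mean_relative_peak", "sem_peak"]])
    ctrl_auc = np.mean([p.auc for p in profiles if p.condition_id == control and not p.no_aggregation])
    ctrl_peak = np.mean(
        [p.phi_peak for p in profiles if p.condition_id == control and not p.no_aggregation]
    )
    for pr in profiles:
        pr.relative_auc = float(pr.auc / ctrl_auc)
        pr.relative_peak = float(pr.phi_peak / ctrl_peak)
    return out
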