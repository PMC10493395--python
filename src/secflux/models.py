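"""Closed-form kinetic model functions for secondary-nucleation-dominated aggregation.

This module is the single home of the generalized-logistic description of the
fibril mass concentration M(t),

    M(t)/mtot = 1 - (1 + (a/c) * exp(kappa*t))**(-c),

its analytic first and second time derivatives, the half-time closed form, and
the relation a = lambda**2 / (2*kappa**2) between the fitting parameter ``a``
and the primary-process rate combination ``lambda``.  ``kappa`` is the
effective secondary-process rate (units 1/h); ``c`` is a dimensionless shape
parameter, fixed by convention at 0.3 (corresponding to a secondary-nucleation
reaction order of 4, stored as metadata only).

All functions are vectorized over ``t`` and numerically stable for large
``kappa*t`` (evaluation goes through log1p/softplus rather than raw
exponentials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "LogisticParams",
    "logistic_mass",
    "monomer_mass",
    "logistic_derivatives",
    "half_time",
    "lambda_from_a",
    "a_from_lambda",
]


@dataclass
class LogisticParams:
    """Parameters of the generalized logistic fibril-growth curve.

    Attributes
    ----------
    a : float
        Dimensionless fitting parameter (> 0); encodes the primary-process
        contribution through ``a = lambda**2 / (2 * kappa**2)``.
    kappa : float
        Effective secondary-process rate, 1/h (> 0).
    c : float
        Shape parameter in (0, 1]; default 0.3.
    mtot : float
        Total monomer concentration.  1.0 for normalized data, or muM.
    n2 : int
        Secondary-nucleation reaction order.  Metadata only; not used in any
        computation (the printed relation between c and n2 is not recoverable,
        c is treated as a configuration constant).
    """

    a: float
    kappa: float
    c: float = 0.3
    mtot: float = 1.0
    n2: int = field(default=4, compare=False)

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"a must be > 0, got {self.a}")
        if not (self.kappa > 0):
            raise ParameterError(f"kappa must be > 0, got {self.kappa}")
        if not (0 < self.c <= 1):
            raise ParameterError(f"c must be in (0, 1], got {self.c}")
        if not (self.mtot > 0):
            raise ParameterError(f"mtot must be > 0, got {self.mtot}")

    @property
    def lambda_(self) -> float:
        """Primary-process rate combination lambda = kappa*sqrt(2a), 1/h."""
        return lambda_from_a(self.a, self.kappa)

    @classmethod
    def from_lambda(
        cls, lambda_: float, kappa: float, c: float = 0.3, mtot: float = 1.0
    ) -> "LogisticParams":
        return cls(a=a_from_lambda(lambda_, kappa), kappa=kappa, c=c, mtot=mtot)


def _z(t: np.ndarray, p: LogisticParams) -> np.ndarray:
    # z = log((a/c) * exp(kappa t)); the whole model is a function of z.
    return np.log(p.a / p.c) + p.kappa * np.asarray(t, dtype=float)


def logistic_mass(t, p: LogisticParams):
    """Fibril mass M(t), same units as ``p.mtot``.

    Stable at both extremes: M -> 0 as t -> -inf and M -> mtot as t -> +inf.
    """
    z = _z(t, p)
    # M = mtot * (1 - exp(-c * log(1 + e^z)));  log(1+e^z) = logaddexp(0, z)
    return p.mtot * (-np.expm1(-p.c * np.logaddexp(0.0, z)))


def monomer_mass(t, p: LogisticParams):
    """Free monomer m(t) = mtot - M(t) (mass conservation)."""
    z = _z(t, p)
    return p.mtot * np.exp(-p.c * np.logaddexp(0.0, z))


def logistic_derivatives(t, p: LogisticParams):
    """Analytic (dM/dt, d2M/dt2) of the generalized logistic curve.

    dM/dt  = mtot * a * kappa   * e^{kt} * (1+u)^{-c-1}
    d2M/dt2= mtot * a * kappa^2 * e^{kt} * (1+u)^{-c-2} * (1 - c*u)

    with u = (a/c) e^{kt}.  Both are evaluated in log space so that large
    ``kappa*t`` does not overflow; dM/dt > 0 everywhere.
    """
    t = np.asarray(t, dtype=float)
    z = _z(t, p)
    softplus = np.logaddexp(0.0, z)
    log_d1 = np.log(p.a * p.kappa) + p.kappa * t - (p.c + 1.0) * softplus
    d1 = p.mtot * np.exp(log_d1)
    # (1 - c*u)/(1 + u), computed from whichever of u, 1/u is small
    w_pos = np.exp(-np.maximum(z, 0.0))  # 1/u where z > 0
    w_neg = np.exp(np.minimum(z, 0.0))  # u where z <= 0
    ratio = np.where(
        z > 0,
        (w_pos - p.c) / (w_pos + 1.0),
        (1.0 - p.c * w_neg) / (1.0 + w_neg),
    )
    d2 = d1 * p.kappa * ratio
    return d1, d2


def half_time(p: LogisticParams) -> float:
    """Time at which M(t) reaches mtot/2.

    Closed form: t_half = (1/kappa) * ln[(c/a) * (2**(1/c) - 1)].
    Strictly decreasing in kappa for fixed (a, c).
    """
    return float(np.log((p.c / p.a) * (2.0 ** (1.0 / p.c) - 1.0)) / p.kappa)


def lambda_from_a(a: float, kappa: float) -> float:
    """lambda = kappa * sqrt(2 a); inverse of :func:`a_from_lambda`."""
    if not (a > 0) or not (kappa > 0):
        raise ParameterError(f"a and kappa must be > 0, got a={a}, kappa={kappa}")
    return float(kappa * np.sqrt(2.0 * a))


def a_from_lambda(lambda_: float, kappa: float) -> float:
    """a = lambda**2 / (2 kappa**2); inverse of :func:`lambda_from_a`."""
    if not (lambda_ > 0) or not (kappa > 0):
        raise ParameterError(
            f"lambda and kappa must be > 0, got lambda={lambda_}, kappa={kappa}"
        )
    return float(lambda_**2 / (2.0 * kappa**2))
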