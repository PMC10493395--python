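"""Initial-slope extraction from elongation-dominated traces.

With a high seed load (~10% preformed fibrils) aggregation is dominated by
fibril elongation, and the early rise of the normalized signal is linear with
slope 2*k_plus*P(0)*m(0).  The slope over an early-time window is therefore an
effective elongation rate; relative elongation rates versus the vehicle
control cancel the unknown constants P(0) and m(0) when those are shared
across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitError, ParameterError, WindowError
from .relative import build_value_frame, relative_table
from .traces import KineticTrace

__all__ = [
    "InitialSlopeModel",
    "ElongationFit",
    "select_initial_window",
    "fit_elongation",
    "relative_elongation",
]


@dataclass
class ElongationFit:
    """Linear fit to the initial phase of an elongation-dominated trace."""

    slope: float
    intercept: float
    window: tuple[int, int]
    r_plus: float
    no_growth: bool = False
    condition_id: str = ""
    compound_dose: float = 0.0
    replicate: tuple[int, int] = (1, 1)
    relative_value: float | None = field(default=None, compare=False)


def select_initial_window(
    trace: KineticTrace,
    rise_fraction: float = 0.3,
    plateau_window: int = 5,
    min_points: int = 3,
) -> tuple[int, int]:
    """Largest prefix of points with signal <= rise_fraction * plateau.

    The plateau reference is the mean of the last ``plateau_window`` points
    (~1 for normalized traces).  ``rise_fraction=1.0`` admits the whole trace.
    Raises :class:`WindowError` when fewer than ``min_points`` qualify (e.g.
    a trace that starts above the threshold) — adjust ``rise_fraction``.
    """
    if not (0 < rise_fraction <= 1.0):
        raise ParameterError(f"rise_fraction must be in (0, 1], got {rise_fraction}")
    plateau = float(trace.signal[-plateau_window:].mean())
    threshold = rise_fraction * plateau
    above = trace.signal > threshold + 1e-12
    end = int(np.argmax(above)) if above.any() else trace.n_points
    if end < min_points:
        raise WindowError(
            f"only {end} points below {rise_fraction:g} of plateau in trace "
            f"{trace._label()}; need >= {min_points}. Adjust rise_fraction."
        )
    return (0, end)


def select_duration_window(
    trace: KineticTrace, max_time: float = 2.0, min_points: int = 3
) -> tuple[int, int]:
    """Fixed-duration alternative: all points with t <= max_time hours."""
    end = int(np.searchsorted(trace.time, max_time, side="right"))
    if end < min_points:
        raise WindowError(
            f"only {end} points within the first {max_time:g} h of trace "
            f"{trace._label()}; need >= {min_points}"
        )
    return (0, end)


class InitialSlopeModel(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares line through the early phase of a trace.

    ``fit(t, y)`` fits ``y = slope * t + intercept`` on the window selected by
    ``window_mode`` ('fraction': prefix below ``rise_fraction`` of the plateau;
    'duration': the first ``max_time`` hours); ``predict(t)`` evaluates the line.

    Attributes: ``slope_``, ``intercept_``, ``window_``.
    """

    def __init__(
        self,
        rise_fraction: float = 0.3,
        window_mode: str = "fraction",
        max_time: float = 2.0,
        plateau_window: int = 5,
        min_points: int = 3,
    ) -> None:
        self.rise_fraction = rise_fraction
        self.window_mode = window_mode
        self.max_time = max_time
        self.plateau_window = plateau_window
        self.min_points = min_points

    def fit(self, t, y, window: tuple[int, int] | None = None) -> "InitialSlopeModel":
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if window is None:
            trace_like = KineticTrace(time=t, signal=y, is_normalized=False)
            if self.window_mode == "fraction":
                window = select_initial_window(
                    trace_like, self.rise_fraction, self.plateau_window, self.min_points
                )
            elif self.window_mode == "duration":
                window = select_duration_window(trace_like, self.max_time, self.min_points)
            else:
                raise ParameterError(
                    f"window_mode must be 'fraction' or 'duration', got {self.window_mode!r}"
                )
        lo, hi = window
        tw, yw = t[lo:hi], y[lo:hi]
        if np.unique(tw).size < 2:
            raise FitError("singular design: fewer than 2 distinct times in window")
        slope, intercept = np.polyfit(tw, yw, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.window_ = (int(lo), int(hi))
        return self

    def predict(self, t):
        return self.slope_ * np.asarray(t, dtype=float).ravel() + self.intercept_


def fit_elongation(
    trace: KineticTrace,
    window: tuple[int, int] | None = None,
    rise_fraction: float = 0.3,
    **kwargs,
) -> ElongationFit:
    """OLS initial slope of one trace; the slope is the effective elongation rate."""
    est = InitialSlopeModel(rise_fraction=rise_fraction, **kwargs).fit(
        trace.time, trace.signal, window=window
    )
    return ElongationFit(
        slope=est.slope_,
        intercept=est.intercept_,
        window=est.window_,
        r_plus=est.slope_,
        no_growth=not (est.slope_ > 0),
        condition_id=trace.condition_id,
        compound_dose=trace.compound_dose,
        replicate=trace.replicate,
    )


def no_growth_elongation(trace_like) -> ElongationFit:
    """Zero-slope placeholder for a flat (fully inhibited) trace."""
    return ElongationFit(
        slope=0.0,
        intercept=0.0,
        window=(0, 0),
        r_plus=0.0,
        no_growth=True,
        condition_id=trace_like.condition_id,
        compound_dose=trace_like.compound_dose,
        replicate=trace_like.replicate,
    )


def relative_elongation(fits: Iterable[ElongationFit], control: str):
    """Per-condition mean relative elongation rate + SEM versus the control."""
    fits = list(fits)
    values = build_value_frame(
        {
            "condition_id": f.condition_id,
            "compound_dose": f.compound_dose,
            "experiment": f.replicate[0],
            "value": max(f.slope, 0.0) if f.no_growth else f.slope,
            "complete_inhibition": f.no_growth,
        }
        for f in fits
    )
    table = relative_table(values, control)
    ctrl_mean = values.loc[
        (values["condition_id"] == control) & ~values["complete_inhibition"], "value"
    ].mean()
    for f in fits:
        f.relative_value = float((0.0 if f.no_growth else f.slope) / ctrl_mean)
    return table
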