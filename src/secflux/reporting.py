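"""Condition summaries: control-relative means, SEM, and multiplicity-adjusted
significance versus the vehicle control.

The statistical convention mirrors the standard plate-assay report: ordinary
one-way ANOVA across conditions, followed by many-to-one comparisons against
the DMSO control with familywise adjustment.  The default adjustment is
Dunnett's test (the comparisons of interest are all against the control);
Bonferroni-corrected Welch t-tests are selectable.  Significance bands:
'*' p<=0.05, '**' p<=0.01, '***' p<=0.001, '****' p<=0.0001 (the single-star
band is included by standard convention).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, NormalizationError, ParameterError
from .relative import relative_table

__all__ = ["stars", "anova_vs_control", "summarize"]

_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p_adjusted: float) -> str:
    """Significance band for an adjusted p-value ('' when p > 0.05 or NaN)."""
    if not np.isfinite(p_adjusted):
        return ""
    if not (0 <= p_adjusted <= 1):
        raise ParameterError(f"p-value must lie in [0, 1], got {p_adjusted}")
    for cut, band in _BANDS:
        if p_adjusted <= cut:
            return band
    return ""


def anova_vs_control(
    groups: Mapping[str, np.ndarray],
    control: str,
    method: str = "dunnett",
    random_state: int = 0,
) -> dict:
    """One-way ANOVA plus familywise-adjusted many-to-one comparisons.

    Parameters
    ----------
    groups : mapping condition -> experiment-level values (each n >= 2)
    control : key of the control group
    method : 'dunnett' (default) or 'bonferroni'
    random_state : seed of the multivariate-t integration in Dunnett's test
        (fixed for reproducibility)

    Returns a dict with ``f_statistic``, ``p_anova`` and ``p_adjusted``
    (mapping of each non-control condition to its adjusted p-value).
    """
    if control not in groups:
        raise NormalizationError(f"control group {control!r} not present")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ParameterError(f"group {k!r} has {v.size} value(s); need >= 2")
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise DegenerateVarianceError("zero within-group variance in every group")

    ctrl = arrays[control]
    others = {k: v for k, v in arrays.items() if k != control}
    f_stat, p_anova = stats.f_oneway(*arrays.values())

    if method == "dunnett":
        res = stats.dunnett(
            *others.values(),
            control=ctrl,
            random_state=np.random.default_rng(random_state),
        )
        p_adj = dict(zip(others.keys(), (float(p) for p in res.pvalue)))
    elif method == "bonferroni":
        m = len(others)
        p_adj = {
            k: float(min(1.0, stats.ttest_ind(v, ctrl).pvalue * m))
            for k, v in others.items()
        }
    else:
        raise ParameterError(f"method must be 'dunnett' or 'bonferroni', got {method!r}")
    return {"f_statistic": float(f_stat), "p_anova": float(p_anova), "p_adjusted": p_adj}


def summarize(
    values: pd.DataFrame,
    control: str,
    metric_name: str,
    method: str = "dunnett",
    random_state: int = 0,
) -> pd.DataFrame:
    """Full condition-summary table for one metric.

    ``values`` holds one row per (condition, experiment) with columns
    ``condition_id``, ``compound_dose``, ``experiment``, ``value`` and
    ``complete_inhibition``.  Ratios are taken versus the control mean; SEM
    over experiment-level values.  Complete-inhibition conditions are reported
    with relative value 0 and are excluded from significance testing (their
    variance is degenerate by construction), as is the control itself.

    Returns one row per condition: condition_id (index), compound_dose,
    metric_name, mean_relative, sem, n, complete_inhibition, p_adjusted,
    stars — invariant to condition ordering.
    """
    table = relative_table(values, control).copy()
    table.insert(0, "metric_name", metric_name)

    testable = {
        cond: grp["value"].to_numpy(dtype=float)
        for cond, grp in values.groupby("condition_id")
        if not grp["complete_inhibition"].all() and len(grp) >= 2
    }
    table["p_adjusted"] = np.nan
    if control in testable and len(testable) >= 2:
        try:
            result = anova_vs_control(testable, control, method, random_state)
        except DegenerateVarianceError:
            result = None
        if result is not None:
            for cond, p in result["p_adjusted"].items():
                table.loc[cond, "p_adjusted"] = p
    table["stars"] = [stars(p) for p in table["p_adjusted"]]
    return table
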