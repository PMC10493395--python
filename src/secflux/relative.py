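"""Control-normalized rate tables shared by all fit modules.

Every headline readout of the pipeline (fibril amplification, elongation,
lipid-induced nucleation, oligomer-flux metrics) is reported relative to the
vehicle (DMSO) control: each per-experiment value is divided by the mean of
the control's per-experiment values, then summarized per condition as mean
relative value with SEM across experiments.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import NormalizationError

__all__ = ["relative_table", "build_value_frame"]

VALUE_COLUMNS = ["condition_id", "compound_dose", "experiment", "value", "complete_inhibition"]


def build_value_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-(condition, experiment) values into the canonical frame."""
    df = pd.DataFrame(list(records))
    for col, default in (("compound_dose", 0.0), ("complete_inhibition", False)):
        if col not in df.columns:
            df[col] = default
    return df[VALUE_COLUMNS]


def relative_table(values: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-condition mean relative value and SEM versus the control mean.

    Parameters
    ----------
    values : frame with columns condition_id, compound_dose, experiment,
        value, complete_inhibition (one row per experiment-level replicate;
        complete-inhibition replicates carry value 0).
    control : condition_id of the vehicle control.

    Returns a frame indexed by condition with columns ``compound_dose``,
    ``mean_relative``, ``sem``, ``n`` and ``complete_inhibition`` (true when
    every replicate of the condition was flagged).  SEM uses the n-1
    denominator across experiment-level replicates; a single replicate gives
    NaN SEM.
    """
    if values.empty:
        raise NormalizationError("no values to normalize")
    ctrl = values[values["condition_id"] == control]
    if ctrl.empty:
        raise NormalizationError(f"control condition {control!r} not present")
    ctrl_ok = ctrl[~ctrl["complete_inhibition"]]
    if ctrl_ok.empty or not np.isfinite(ctrl_ok["value"]).any():
        raise NormalizationError(
            f"control condition {control!r} has no converged replicates to normalize by"
        )
    ctrl_mean = float(ctrl_ok["value"].mean())
    if ctrl_mean <= 0:
        raise NormalizationError(
            f"control mean value must be positive, got {ctrl_mean:g}"
        )

    rows = []
    for cond, grp in values.groupby("condition_id", sort=True):
        rel = grp["value"].to_numpy(dtype=float) / ctrl_mean
        n = rel.size
        sem = float(np.std(rel, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {
                "condition_id": cond,
                "compound_dose": float(grp["compound_dose"].iloc[0]),
                "mean_relative": float(rel.mean()),
                "sem": sem,
                "n": int(n),
                "complete_inhibition": bool(grp["complete_inhibition"].all()),
            }
        )
    table = pd.DataFrame(rows).set_index("condition_id")
    return table.sort_values("compound_dose")
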