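"""Plate-reader kinetic trace containers, long-form CSV I/O, normalization and
replicate aggregation.

The canonical on-disk layout is a long-form CSV with one row per
(well, timepoint) and columns::

    time_h, signal, condition, dose_moleq, experiment, technical, assay

Time is in hours throughout, concentrations in muM, compound doses in molar
equivalents relative to monomer.  A wide-format signal matrix plus a plate
layout CSV (well -> condition map) is accepted as an alternative input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    GridError,
    NoGrowthError,
    ParameterError,
    SchemaError,
    TraceValidationError,
)

__all__ = [
    "ASSAY_KINDS",
    "KineticTrace",
    "AssayCondition",
    "AggregatedTrace",
    "read_traces",
    "write_traces",
    "read_wide_plate",
    "traces_to_frame",
    "frame_to_traces",
    "normalize_trace",
    "normalize_signal",
    "aggregate_replicates",
]

ASSAY_KINDS = frozenset({"secondary", "elongation", "lipid", "nephelometry"})

#: canonical column names of the long-form CSV dialect
CANONICAL_COLUMNS = (
    "time_h",
    "signal",
    "condition",
    "dose_moleq",
    "experiment",
    "technical",
    "assay",
)
_REQUIRED = ("time_h", "signal", "condition")


@dataclass
class KineticTrace:
    """One fluorescence/nephelometry time course with its annotations.

    ``time`` (hours) must be strictly increasing and of the same length as
    ``signal`` (arbitrary units), with at least 5 points.  Normalized traces
    must lie in [-0.1, 1.1] (small noise excursions allowed).
    """

    time: np.ndarray
    signal: np.ndarray
    assay_kind: str = "secondary"
    condition_id: str = ""
    compound_dose: float = 0.0
    replicate: tuple[int, int] = (1, 1)
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.assay_kind not in ASSAY_KINDS:
            raise TraceValidationError(
                f"unknown assay_kind {self.assay_kind!r}; expected one of {sorted(ASSAY_KINDS)}"
            )
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise TraceValidationError("time and signal must be 1-D vectors")
        if self.time.size != self.signal.size:
            raise TraceValidationError(
                f"time ({self.time.size}) and signal ({self.signal.size}) lengths differ"
            )
        if self.time.size < 5:
            raise TraceValidationError(
                f"trace {self._label()} has {self.time.size} points; at least 5 required"
            )
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.signal)):
            raise TraceValidationError(f"trace {self._label()} contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise TraceValidationError(
                f"time is not strictly increasing in trace {self._label()}"
            )
        if self.is_normalized and (
            self.signal.min() < -0.1 or self.signal.max() > 1.1
        ):
            raise TraceValidationError(
                f"normalized trace {self._label()} has values outside [-0.1, 1.1]"
            )

    def _label(self) -> str:
        e, r = self.replicate
        return f"(condition={self.condition_id!r}, experiment={e}, technical={r})"

    @property
    def n_points(self) -> int:
        return int(self.time.size)


@dataclass
class AssayCondition:
    """Chemical context of one analysis condition.

    ``mtot`` is the total monomer concentration (muM), ``seed_percent`` the
    preformed-fibril concentration as a percentage of monomer, ``lipid_conc``
    the DMPS vesicle concentration (muM) where applicable.  Exactly one
    condition per analysis set should carry ``control_flag`` (the DMSO
    vehicle control).
    """

    mtot: float
    seed_percent: float = 0.0
    lipid_conc: float | None = None
    buffer_label: str = ""
    control_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.mtot > 0):
            raise ParameterError(f"mtot must be > 0, got {self.mtot}")
        if self.seed_percent < 0:
            raise ParameterError(f"seed_percent must be >= 0, got {self.seed_percent}")


@dataclass
class AggregatedTrace:
    """Mean trace with per-timepoint SEM over replicates."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    level: str
    sem_defined: bool = True
    condition_id: str = ""
    compound_dose: float = 0.0
    assay_kind: str = "secondary"
    is_normalized: bool = False
    experiment: int | None = None

    def to_trace(self) -> KineticTrace:
        """The mean as a plain :class:`KineticTrace` (SEM dropped)."""
        exp = self.experiment if self.experiment is not None else 0
        return KineticTrace(
            time=self.time,
            signal=self.mean,
            assay_kind=self.assay_kind,
            condition_id=self.condition_id,
            compound_dose=self.compound_dose,
            replicate=(exp, 0),
            is_normalized=self.is_normalized,
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in input")
    defaults = {"dose_moleq": 0.0, "experiment": 1, "technical": 1, "assay": "secondary"}
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df


def read_traces(
    path: str | os.PathLike, schema: Mapping[str, str] | None = None
) -> list[KineticTrace]:
    """Read a long-form CSV into one :class:`KineticTrace` per (condition, replicate).

    Parameters
    ----------
    path : path to a CSV file
    schema : optional mapping from canonical column names (``time_h`` etc.) to
        the column names actually present in the file.

    Rows are ordered by time within each group; a duplicated timepoint within
    a group raises :class:`TraceValidationError` naming the group.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file contains no data") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: file contains no rows")
    df = _apply_schema(df, schema)
    return frame_to_traces(df)


def frame_to_traces(df: pd.DataFrame) -> list[KineticTrace]:
    """Group a long-form DataFrame into a list of traces (sorted by group key)."""
    keys = ["condition", "dose_moleq", "experiment", "technical", "assay"]
    traces: list[KineticTrace] = []
    for key, grp in df.groupby(keys, sort=True):
        cond, dose, exp, tech, assay = key
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TraceValidationError(
                f"duplicated or non-increasing timepoints in group "
                f"(condition={cond!r}, experiment={exp}, technical={tech})"
            )
        traces.append(
            KineticTrace(
                time=t,
                signal=grp["signal"].to_numpy(dtype=float),
                assay_kind=str(assay),
                condition_id=str(cond),
                compound_dose=float(dose),
                replicate=(int(exp), int(tech)),
                is_normalized=bool(grp["normalized"].iloc[0])
                if "normalized" in grp.columns
                else False,
            )
        )
    return traces


def traces_to_frame(traces: Iterable[KineticTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "time_h": tr.time,
                    "signal": tr.signal,
                    "condition": tr.condition_id,
                    "dose_moleq": tr.compound_dose,
                    "experiment": tr.replicate[0],
                    "technical": tr.replicate[1],
                    "assay": tr.assay_kind,
                    "normalized": tr.is_normalized,
                }
            )
        )
    if not rows:
        raise EmptyInputError("no traces to write")
    return pd.concat(rows, ignore_index=True)


def write_traces(traces: Iterable[KineticTrace], path: str | os.PathLike) -> None:
    """Write traces in the long-form CSV dialect (header, '.' decimals)."""
    traces_to_frame(traces).to_csv(path, index=False)


def read_wide_plate(
    signal_path: str | os.PathLike, layout_path: str | os.PathLike
) -> list[KineticTrace]:
    """Read a wide-format signal matrix plus a plate-layout CSV.

    The signal file has a ``time_h`` column and one column per well; the
    layout file maps ``well`` to ``condition`` (and optionally ``dose_moleq``,
    ``experiment``, ``technical``, ``assay``).
    """
    sig = pd.read_csv(signal_path)
    if sig.empty:
        raise EmptyInputError(f"{signal_path}: file contains no rows")
    if "time_h" not in sig.columns:
        raise SchemaError("required column 'time_h' not found in signal matrix")
    layout = pd.read_csv(layout_path)
    for col in ("well", "condition"):
        if col not in layout.columns:
            raise SchemaError(f"required column {col!r} not found in plate layout")
    layout = layout.set_index("well")
    long_rows = []
    for well in sig.columns:
        if well == "time_h":
            continue
        if well not in layout.index:
            raise SchemaError(f"well {well!r} in signal matrix missing from plate layout")
        meta = layout.loc[well]
        long_rows.append(
            pd.DataFrame(
                {
                    "time_h": sig["time_h"],
                    "signal": sig[well],
                    "condition": meta["condition"],
                    "dose_moleq": float(meta.get("dose_moleq", 0.0)),
                    "experiment": int(meta.get("experiment", 1)),
                    "technical": int(meta.get("technical", 1)),
                    "assay": meta.get("assay", "secondary"),
                }
            )
        )
    if not long_rows:
        raise EmptyInputError(f"{signal_path}: no well columns found")
    return frame_to_traces(pd.concat(long_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Normalization


def normalize_signal(
    signal: np.ndarray,
    baseline_window: int = 3,
    plateau_window: int = 5,
    min_rise_sigmas: float = 4.0,
    label: str = "",
) -> np.ndarray:
    """Windowed affine normalization of a raw signal vector.

    Shared engine of :func:`normalize_trace`; raises :class:`NoGrowthError`
    when the plateau does not rise above the baseline (see there).  Useful
    when the caller averages several normalized wells before constructing a
    validated trace.
    """
    signal = np.asarray(signal, dtype=float)
    b, p = int(baseline_window), int(plateau_window)
    if b < 1 or p < 1:
        raise ParameterError("baseline_window and plateau_window must be >= 1")
    if b + p > signal.size:
        raise ParameterError(
            f"windows overlap: baseline {b} + plateau {p} > {signal.size} points"
        )
    head = signal[:b]
    tail = signal[-p:]
    baseline = float(head.mean())
    plateau = float(tail.mean())
    dof = b + p - 2
    if dof > 0:
        pooled_var = (
            np.sum((head - baseline) ** 2) + np.sum((tail - plateau) ** 2)
        ) / dof
        se_diff = np.sqrt(pooled_var * (1.0 / b + 1.0 / p))
    else:
        se_diff = 0.0
    if plateau - baseline <= min_rise_sigmas * se_diff:
        raise NoGrowthError(
            f"no signal growth in trace {label}: plateau {plateau:.4g} "
            f"does not exceed baseline {baseline:.4g} by more than "
            f"{min_rise_sigmas:g} sigma"
        )
    return (signal - baseline) / (plateau - baseline)


def normalize_trace(
    trace: KineticTrace,
    baseline_window: int = 3,
    plateau_window: int = 5,
    min_rise_sigmas: float = 4.0,
) -> KineticTrace:
    """Affinely rescale a raw trace so baseline -> 0 and plateau -> 1.

    baseline = mean of the first ``baseline_window`` points, plateau = mean of
    the last ``plateau_window`` points; output = (signal - baseline) /
    (plateau - baseline).  The transform is invariant to positive scaling of
    the raw signal (so a fluorophore quench, e.g. the ~23% quench measured at
    the top compound dose, cancels exactly) and idempotent on its own output.

    A trace whose plateau does not rise above its baseline by more than
    ``min_rise_sigmas`` standard errors of the window difference raises
    :class:`NoGrowthError` — the caller decides whether this is complete
    inhibition of aggregation.
    """
    scaled = normalize_signal(
        trace.signal, baseline_window, plateau_window, min_rise_sigmas,
        label=trace._label(),
    )
    return replace(trace, signal=scaled, is_normalized=True)


# ---------------------------------------------------------------------------
# Replicate aggregation


def _common_grid(
    traces: Sequence[KineticTrace], interpolate: bool
) -> tuple[np.ndarray, list[np.ndarray]]:
    t0 = traces[0].time
    if all(np.array_equal(tr.time, t0) for tr in traces):
        return t0, [tr.signal for tr in traces]
    if not interpolate:
        raise GridError(
            "traces do not share a common time grid; pass interpolate=True to "
            "resample onto the union grid"
        )
    union = np.unique(np.concatenate([tr.time for tr in traces]))
    return union, [np.interp(union, tr.time, tr.signal) for tr in traces]


def _mean_sem(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
        return mean, sem, True
    return mean, np.full(mean.shape, np.nan), False


def aggregate_replicates(
    traces: Sequence[KineticTrace],
    level: str = "technical",
    interpolate: bool = False,
) -> AggregatedTrace:
    """Mean trace and per-timepoint SEM over a set of replicate traces.

    ``level='technical'`` averages every trace in the collection with equal
    weight.  ``level='experimental'`` first averages technical replicates
    within each experiment, then reports mean and SEM across experiment means
    (SEM uses the n-1 denominator over n series).  A single series at the
    experimental level yields NaN SEM with ``sem_defined=False`` rather than
    an error.
    """
    traces = list(traces)
    if not traces:
        raise EmptyInputError("no traces to aggregate")
    if level not in ("technical", "experimental"):
        raise ParameterError(f"level must be 'technical' or 'experimental', got {level!r}")
    grid, signals = _common_grid(traces, interpolate)
    meta = traces[0]
    if level == "technical":
        stack = np.vstack(signals)
    else:
        by_exp: dict[int, list[np.ndarray]] = {}
        for tr, sig in zip(traces, signals):
            by_exp.setdefault(tr.replicate[0], []).append(sig)
        stack = np.vstack([np.vstack(sigs).mean(axis=0) for sigs in by_exp.values()])
    mean, sem, defined = _mean_sem(stack)
    return AggregatedTrace(
        time=grid,
        mean=mean,
        sem=sem,
        n=stack.shape[0],
        level=level,
        sem_defined=defined,
        condition_id=meta.condition_id,
        compound_dose=meta.compound_dose,
        assay_kind=meta.assay_kind,
        is_normalized=all(tr.is_normalized for tr in traces),
        experiment=meta.replicate[0] if level == "technical" else None,
    )
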