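"""End-to-end analyses: raw trace collections in, condition summaries out.

Each ``analyze_*`` function implements the full chain the assay calls for:

1. group raw traces by (condition, experiment);
2. normalize per well (default) or after technical averaging, treating
   no-growth traces as complete inhibition;
3. average technical replicates within each experiment;
4. fit each experiment-level trace;
5. report condition summaries relative to the vehicle control with SEM over
   experiments and Dunnett-adjusted significance.

The oligomer-flux analysis composes a secondary analysis with per-condition
effective elongation rates (from a matched elongation analysis or supplied
directly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .elongation import (
    ElongationFit,
    fit_elongation,
    no_growth_elongation,
    relative_elongation,
)
from .exceptions import NoGrowthError, ParameterError, WindowError
from .flux import FluxProfile, flux_profile, relative_flux_metrics
from .lipid import LipidFit, fit_lipid_early, no_growth_lipid, relative_lipid_rate
from .relative import build_value_frame
from .reporting import summarize
from .secondary import (
    AmplificationRate,
    LogisticFit,
    amplification_rate,
    fit_secondary,
    no_aggregation_fit,
    relative_amplification,
)
from .traces import (
    KineticTrace,
    aggregate_replicates,
    normalize_signal,
    normalize_trace,
)

__all__ = [
    "SecondaryAnalysis",
    "ElongationAnalysis",
    "LipidAnalysis",
    "FluxAnalysis",
    "analyze_secondary",
    "analyze_elongation",
    "analyze_lipid",
    "analyze_flux",
    "experiment_traces",
]


def experiment_traces(
    traces: Iterable[KineticTrace],
    normalize: str = "per_well",
    baseline_window: int = 3,
    plateau_window: int = 5,
) -> list[KineticTrace | None]:
    """Normalize and reduce technical replicates to one trace per experiment.

    ``normalize='per_well'`` (default) normalizes each well before averaging;
    ``'per_experiment'`` averages raw technicals first, then normalizes the
    mean trace.  An experiment whose traces show no growth yields ``None`` in
    the returned list (complete inhibition), tagged with metadata via the
    parallel key list — callers receive (key, trace-or-None) pairs.
    """
    if normalize not in ("per_well", "per_experiment"):
        raise ParameterError(
            f"normalize must be 'per_well' or 'per_experiment', got {normalize!r}"
        )
    groups: dict[tuple[str, float, int], list[KineticTrace]] = {}
    for tr in traces:
        key = (tr.condition_id, tr.compound_dose, tr.replicate[0])
        groups.setdefault(key, []).append(tr)

    out = []
    for key in sorted(groups, key=lambda k: (k[1], k[0], k[2])):
        members = groups[key]
        try:
            if normalize == "per_well":
                # normalize each well's signal array, then average; only the
                # experiment mean becomes a validated KineticTrace
                import numpy as np

                normed = np.vstack(
                    [
                        normalize_signal(
                            tr.signal, baseline_window, plateau_window,
                            label=tr._label(),
                        )
                        for tr in members
                    ]
                )
                first = members[0]
                mean_trace = KineticTrace(
                    time=first.time,
                    signal=normed.mean(axis=0),
                    assay_kind=first.assay_kind,
                    condition_id=first.condition_id,
                    compound_dose=first.compound_dose,
                    replicate=(key[2], 0),
                    is_normalized=True,
                )
            else:
                agg = aggregate_replicates(members, level="technical")
                mean_trace = normalize_trace(
                    agg.to_trace(), baseline_window, plateau_window
                )
            out.append((key, mean_trace))
        except NoGrowthError:
            out.append((key, None))
    return out


@dataclass
class SecondaryAnalysis:
    fits: list[LogisticFit]
    rates: list[AmplificationRate]
    amplification: pd.DataFrame
    half_times: pd.DataFrame
    control: str


@dataclass
class ElongationAnalysis:
    fits: list[ElongationFit]
    table: pd.DataFrame
    control: str

    def r_plus_by_condition(self) -> dict[str, float]:
        """Per-condition mean relative elongation rate, for the flux module."""
        return {cond: float(v) for cond, v in self.table["mean_relative"].items()}


@dataclass
class LipidAnalysis:
    fits: list[LipidFit]
    table: pd.DataFrame
    control: str


@dataclass
class FluxAnalysis:
    profiles: list[FluxProfile]
    table: pd.DataFrame
    control: str


class _Provenance:
    """Minimal metadata carrier for flagged (no-growth) groups."""

    def __init__(self, key: tuple[str, float, int]) -> None:
        self.condition_id, self.compound_dose, exp = key
        self.replicate = (exp, 0)


def analyze_secondary(
    traces: Iterable[KineticTrace],
    control: str = "DMSO",
    c: float = 0.3,
    k_plus: float = 1.0,
    normalize: str = "per_well",
    anova_method: str = "dunnett",
    baseline_window: int = 15,
    plateau_window: int = 30,
    **fit_config,
) -> SecondaryAnalysis:
    """Seeded secondary-nucleation pipeline: logistic fits, amplification
    rates, relative half-times, Dunnett significance.

    The normalization windows default to 15 baseline / 30 plateau points:
    the logistic fit holds the normalized plateau at exactly 1, so a 1%%
    amplitude error from a noisy plateau estimate moves the fitted kappa by
    ~3.7%%; wide windows keep that term below the intrinsic fit noise.
    """
    fits: list[LogisticFit] = []
    for key, tr in experiment_traces(
        traces, normalize=normalize,
        baseline_window=baseline_window, plateau_window=plateau_window,
    ):
        if tr is None:
            fits.append(no_aggregation_fit(_Provenance(key), "no signal growth"))
        else:
            fit_config.setdefault("profile_scale", True)
            fits.append(fit_secondary(tr, c_fixed=c, **fit_config))
    rates = [amplification_rate(f, k_plus=k_plus) for f in fits]
    relative_amplification(rates, control)  # fills relative_value in place
    amp_values = build_value_frame(
        {
            "condition_id": r.condition_id,
            "compound_dose": r.compound_dose,
            "experiment": r.replicate[0],
            "value": r.dP_dt,
            "complete_inhibition": r.complete_inhibition,
        }
        for r in rates
    )
    amp_table = summarize(amp_values, control, "amplification", method=anova_method)
    t_half_values = build_value_frame(
        {
            "condition_id": f.condition_id,
            "compound_dose": f.compound_dose,
            "experiment": f.replicate[0],
            "value": f.t_half if f.t_half is not None else 0.0,
            "complete_inhibition": f.no_aggregation,
        }
        for f in fits
    )
    t_half_table = summarize(t_half_values, control, "t_half", method=anova_method)
    return SecondaryAnalysis(
        fits=fits,
        rates=rates,
        amplification=amp_table,
        half_times=t_half_table,
        control=control,
    )


def analyze_elongation(
    traces: Iterable[KineticTrace],
    control: str = "DMSO",
    rise_fraction: float = 0.3,
    normalize: str = "per_well",
    anova_method: str = "dunnett",
    baseline_window: int = 5,
    plateau_window: int = 10,
    **kwargs,
) -> ElongationAnalysis:
    """Elongation pipeline: initial-slope fits and relative elongation rates.

    Baseline contamination by the early linear rise is absorbed by the OLS
    intercept, so a moderately wide baseline window costs nothing.
    """
    fits: list[ElongationFit] = []
    for key, tr in experiment_traces(
        traces, normalize=normalize,
        baseline_window=baseline_window, plateau_window=plateau_window,
    ):
        if tr is None:
            fits.append(no_growth_elongation(_Provenance(key)))
        else:
            fits.append(fit_elongation(tr, rise_fraction=rise_fraction, **kwargs))
    relative_elongation(fits, control)
    values = build_value_frame(
        {
            "condition_id": f.condition_id,
            "compound_dose": f.compound_dose,
            "experiment": f.replicate[0],
            "value": 0.0 if f.no_growth else f.slope,
            "complete_inhibition": f.no_growth,
        }
        for f in fits
    )
    table = summarize(values, control, "elongation", method=anova_method)
    return ElongationAnalysis(fits=fits, table=table, control=control)


def analyze_lipid(
    traces: Iterable[KineticTrace],
    control: str = "DMSO",
    constants: Mapping[str, float] | None = None,
    window_fraction: float = 0.3,
    normalize: str = "per_well",
    anova_method: str = "dunnett",
    baseline_window: int = 8,
    plateau_window: int = 10,
) -> LipidAnalysis:
    """Lipid-induced pipeline: early-quadratic fits and relative nucleation rates.

    The quadratic start is flat, so the first several points are safe
    baseline; the nuisance intercept of the quadratic fit absorbs what little
    early growth leaks into the baseline estimate.
    """
    fits: list[LipidFit] = []
    for key, tr in experiment_traces(
        traces, normalize=normalize,
        baseline_window=baseline_window, plateau_window=plateau_window,
    ):
        if tr is None:
            fits.append(no_growth_lipid(_Provenance(key), constants))
        else:
            fits.append(fit_lipid_early(tr, constants=constants, window_fraction=window_fraction))
    relative_lipid_rate(fits, control)
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
    table = summarize(values, control, "lipid_rate", method=anova_method)
    return LipidAnalysis(fits=fits, table=table, control=control)


def analyze_flux(
    secondary: SecondaryAnalysis,
    r_plus: Mapping[str, float] | ElongationAnalysis | float = 1.0,
    anova_method: str = "dunnett",
) -> FluxAnalysis:
    """Oligomer-flux pipeline from a secondary analysis and elongation rates.

    ``r_plus`` may be a single shared rate, a mapping condition -> effective
    elongation rate, or an :class:`ElongationAnalysis` whose per-condition
    mean relative rates are used (conditions must match).
    """
    if isinstance(r_plus, ElongationAnalysis):
        r_map = r_plus.r_plus_by_condition()
    elif isinstance(r_plus, Mapping):
        r_map = dict(r_plus)
    else:
        r_map = None  # shared scalar

    profiles: list[FluxProfile] = []
    for fit in secondary.fits:
        if fit.no_aggregation:
            profiles.append(_zero_profile(fit))
            continue
        if r_map is None:
            r = float(r_plus)  # type: ignore[arg-type]
        else:
            if fit.condition_id not in r_map:
                raise ParameterError(
                    f"no elongation rate for condition {fit.condition_id!r}"
                )
            r = r_map[fit.condition_id]
        if not (r > 0):
            profiles.append(_zero_profile(fit))
        else:
            profiles.append(flux_profile(fit, r_plus=r))
    table = relative_flux_metrics(profiles, secondary.control)

    peak_values = build_value_frame(
        {
            "condition_id": p.condition_id,
            "compound_dose": p.compound_dose,
            "experiment": p.replicate[0],
            "value": p.phi_peak,
            "complete_inhibition": p.no_aggregation,
        }
        for p in profiles
    )
    peak_table = summarize(peak_values, secondary.control, "flux_peak", method=anova_method)
    table = table.join(peak_table[["p_adjusted", "stars"]])
    return FluxAnalysis(profiles=profiles, table=table, control=secondary.control)


def _zero_profile(fit: LogisticFit) -> FluxProfile:
    import numpy as np

    grid = np.linspace(0.0, 1.0, 2)
    return FluxProfile(
        t_grid=grid,
        phi=np.zeros_like(grid),
        r_plus=0.0,
        t_peak=float("nan"),
        phi_peak=0.0,
        phi_peak_alt=0.0,
        auc=0.0,
        no_aggregation=True,
        condition_id=fit.condition_id,
        compound_dose=fit.compound_dose,
        replicate=fit.replicate,
    )
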