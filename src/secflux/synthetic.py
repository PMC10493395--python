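"""Synthetic plate-reader datasets with ground-truth manifests.

The generators emulate the statistical structure of the four assay designs
the pipeline analyses:

* seeded secondary-nucleation traces — sigmoidal generalized-logistic curves,
  dose-dependent suppression of the secondary rate ``kappa``, a
  complete-inhibition dose producing flat traces, and a dose-proportional
  fluorophore quench (23% at the top dose);
* elongation-dominated traces — linear early rise clipped at plateau;
* lipid-induced traces — early quadratic growth clipped at plateau;
* supernatant-depletion dose-response tables for binding fits.

Replicate structure follows the study design: ``n_experiments`` experimental
replicates each containing ``n_technical`` technical replicates.  Noise is
additive i.i.d. Gaussian on the normalized scale; experiments additionally
carry a small lognormal jitter (default 3% CV) of the rate parameter, drawn
once per experiment and shared across conditions (a plate-level effect), so
that SEM across experiments is meaningful while control-normalized means
remain unbiased estimators of the programmed dose factors.

Every generator is deterministic under a fixed seed, and its manifest (the
spec dump plus the realized per-experiment parameters) suffices to regenerate
byte-identical data via :func:`regenerate`.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .binding import four_param_logistic
from .models import LogisticParams, logistic_mass

__all__ = [
    "SyntheticSpec",
    "generate_secondary",
    "generate_elongation",
    "generate_lipid",
    "generate_binding",
    "generate_traces",
    "regenerate",
    "preset_secondary",
    "preset_elongation",
    "preset_elongation_matched",
    "preset_lipid",
    "preset_binding",
    "PRESETS",
]

from .traces import KineticTrace

DEFAULT_SEED = 20230828

#: reductions of the amplification rate programmed by the secondary preset
SECONDARY_REDUCTIONS = {0.02: 0.14, 0.05: 0.17, 0.075: 0.37}


class SyntheticSpec(BaseModel):
    """Declarative description of one synthetic dataset.

    ``dose_effects[i]`` multiplies the assay's rate parameter (kappa for
    secondary, slope for elongation, kn for lipid) at ``doses[i]``; a factor
    of 0 programs complete inhibition (flat trace).  ``quench_top`` is the
    fractional fluorophore quench at the maximum dose, interpolated linearly
    in dose.
    """

    assay_kind: Literal["secondary", "elongation", "lipid", "binding"]
    seed: int = DEFAULT_SEED
    noise_sigma: float = Field(default=0.02, ge=0)
    n_experiments: int = Field(default=3, ge=1)
    n_technical: int = Field(default=3, ge=1)
    t_end: float = Field(default=30.0, gt=0)
    n_points: int = Field(default=121, ge=8)
    doses: tuple[float, ...] = (0.0,)
    dose_effects: tuple[float, ...] = (1.0,)
    quench_top: float = Field(default=0.23, ge=0, lt=1)
    baseline: float = 10.0
    plateau_scale: float = 100.0
    jitter_cv: float = Field(default=0.03, ge=0)
    # ground-truth kinetic parameters (per assay kind)
    a: float = Field(default=0.03, gt=0)
    kappa: float = Field(default=0.5, gt=0)
    c: float = Field(default=0.3, gt=0, le=1)
    slope: float = Field(default=0.125, gt=0)
    prefactor: float = Field(default=0.01, gt=0)
    # binding design
    kd: float = Field(default=6.0, gt=0)
    hill: float = Field(default=1.0, gt=0)
    r_min: float = 0.0
    r_max: float = Field(default=10.0, gt=0)
    ligand_min: float = Field(default=0.5, gt=0)
    ligand_max: float = Field(default=50.0, gt=0)
    n_doses: int = Field(default=8, ge=4)
    mult_noise: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        if len(self.doses) != len(self.dose_effects):
            raise ValueError(
                f"doses ({len(self.doses)}) and dose_effects "
                f"({len(self.dose_effects)}) must have the same length"
            )
        if any(f < 0 for f in self.dose_effects):
            raise ValueError("dose_effects must be >= 0 (0 = complete inhibition)")
        if self.ligand_max <= self.ligand_min:
            raise ValueError("ligand_max must exceed ligand_min")
        return self


def condition_label(dose: float) -> str:
    """'DMSO' for the vehicle (zero-dose) control, else the dose in M eq."""
    return "DMSO" if dose == 0 else f"cmpd_{dose:g}"


def _jitters(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.jitter_cv == 0:
        return np.ones(spec.n_experiments)
    sigma_ln = math.sqrt(math.log(1.0 + spec.jitter_cv**2))
    return np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, spec.n_experiments))


def _emit_traces(spec: SyntheticSpec, model_curve) -> tuple[list[KineticTrace], dict]:
    """Shared raw-signal assembly: quench * (scale*M + baseline + scale*noise)."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_end, spec.n_points)
    jitter = _jitters(spec, rng)
    max_dose = max(spec.doses) if max(spec.doses) > 0 else 1.0
    traces: list[KineticTrace] = []
    realized: list[dict] = []
    for dose, factor in zip(spec.doses, spec.dose_effects):
        quench = 1.0 - spec.quench_top * dose / max_dose
        for e in range(spec.n_experiments):
            y_true, truth = model_curve(t, factor, jitter[e])
            realized.append(
                {"condition": condition_label(dose), "dose": dose, "experiment": e + 1, **truth}
            )
            for r in range(spec.n_technical):
                noise = rng.normal(0.0, spec.noise_sigma, t.size)
                raw = quench * (
                    spec.plateau_scale * y_true + spec.baseline + spec.plateau_scale * noise
                )
                traces.append(
                    KineticTrace(
                        time=t,
                        signal=raw,
                        assay_kind=spec.assay_kind if spec.assay_kind != "binding" else "secondary",
                        condition_id=condition_label(dose),
                        compound_dose=dose,
                        replicate=(e + 1, r + 1),
                    )
                )
    manifest = {
        "spec": spec.model_dump(),
        "realized": realized,
        "programmed_relative": {
            condition_label(d): f for d, f in zip(spec.doses, spec.dose_effects)
        },
    }
    return traces, manifest


def generate_secondary(spec: SyntheticSpec) -> tuple[list[KineticTrace], dict]:
    """Seeded secondary-nucleation traces (generalized-logistic forward model).

    A dose factor f multiplies kappa; the programmed relative amplification
    rate is f**2 (dP/dt scales with kappa**2 at fixed a, c).  A factor of 0
    yields a flat trace (complete inhibition).
    """
    assert spec.assay_kind == "secondary"

    def curve(t, factor, jit):
        if factor == 0:
            return np.zeros_like(t), {"kappa": 0.0, "a": spec.a, "flat": True}
        kappa = spec.kappa * factor * jit
        p = LogisticParams(a=spec.a, kappa=kappa, c=spec.c)
        return logistic_mass(t, p), {"kappa": kappa, "a": spec.a, "flat": False}

    traces, manifest = _emit_traces(spec, curve)
    manifest["programmed_relative_amplification"] = {
        condition_label(d): f**2 for d, f in zip(spec.doses, spec.dose_effects)
    }
    return traces, manifest


def generate_elongation(spec: SyntheticSpec) -> tuple[list[KineticTrace], dict]:
    """Elongation-dominated traces: linear ramp clipped at the plateau."""
    assert spec.assay_kind == "elongation"

    def curve(t, factor, jit):
        slope = spec.slope * factor * jit
        return np.clip(slope * t, 0.0, 1.0), {"slope": slope, "flat": factor == 0}

    return _emit_traces(spec, curve)


def generate_lipid(spec: SyntheticSpec) -> tuple[list[KineticTrace], dict]:
    """Lipid-induced traces: early quadratic growth clipped at the plateau."""
    assert spec.assay_kind == "lipid"

    def curve(t, factor, jit):
        C = spec.prefactor * factor * jit
        return np.clip(C * t**2, 0.0, 1.0), {"prefactor": C, "flat": factor == 0}

    return _emit_traces(spec, curve)


def generate_binding(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Supernatant-depletion dose-response table.

    Columns: ligand_uM (= total compound), total_uM, supernatant_uM,
    response_uM (bound compound, the 4PL forward model with multiplicative
    noise on the measured response).
    """
    assert spec.assay_kind == "binding"
    rng = np.random.default_rng(spec.seed)
    L = np.geomspace(spec.ligand_min, spec.ligand_max, spec.n_doses)
    r_true = four_param_logistic(L, spec.r_min, spec.r_max, spec.hill, spec.kd)
    r_obs = r_true * (1.0 + rng.normal(0.0, spec.mult_noise, L.size)) if spec.mult_noise else r_true
    r_obs = np.clip(r_obs, 0.0, None)
    df = pd.DataFrame(
        {
            "ligand_uM": L,
            "total_uM": L,
            "supernatant_uM": np.maximum(L - r_obs, 0.0),
            "response_uM": r_obs,
        }
    )
    manifest = {"spec": spec.model_dump(), "true_response_uM": r_true.tolist()}
    return df, manifest


_GENERATORS = {
    "secondary": generate_secondary,
    "elongation": generate_elongation,
    "lipid": generate_lipid,
    "binding": generate_binding,
}


def generate_traces(spec: SyntheticSpec):
    """Dispatch to the generator for ``spec.assay_kind``."""
    return _GENERATORS[spec.assay_kind](spec)


def regenerate(manifest: dict):
    """Rebuild a dataset byte-identically from its manifest."""
    return generate_traces(SyntheticSpec(**manifest["spec"]))


# ---------------------------------------------------------------------------
# Presets: the default study conditions


def preset_secondary(seed: int = DEFAULT_SEED, **overrides) -> SyntheticSpec:
    """Seeded secondary-nucleation design: 50 muM monomer with 0.06% seeds.

    Doses 0.02/0.05/0.075 M eq programmed to reduce the amplification rate by
    14%/17%/37% (kappa factors sqrt(1-reduction)), plus a flat
    complete-inhibition dose at 0.25 M eq.
    """
    reductions = SECONDARY_REDUCTIONS
    doses = (0.0, *reductions.keys(), 0.25)
    effects = (1.0, *(math.sqrt(1.0 - r) for r in reductions.values()), 0.0)
    kw = dict(
        assay_kind="secondary",
        seed=seed,
        doses=doses,
        dose_effects=effects,
        t_end=60.0,
        n_points=241,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def preset_elongation(seed: int = DEFAULT_SEED, **overrides) -> SyntheticSpec:
    """Elongation design (7% preformed seeds): 26% slope reduction at 0.15 M eq."""
    kw = dict(
        assay_kind="elongation",
        seed=seed,
        doses=(0.0, 0.05, 0.1, 0.15),
        dose_effects=(1.0, 0.97, 0.92, 0.74),
        t_end=14.0,
        n_points=141,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def preset_elongation_matched(seed: int = DEFAULT_SEED, **overrides) -> SyntheticSpec:
    """Elongation rates at the secondary-assay doses, for the flux pipeline.

    The r_plus factors combine with the secondary preset's kappa factors so
    that the oligomer-flux peak (prop. to kappa**2 / r_plus) drops by 14% at
    0.02 and 26% at 0.075 M eq.
    """
    kw = dict(
        assay_kind="elongation",
        seed=seed,
        doses=(0.0, 0.02, 0.05, 0.075),
        dose_effects=(1.0, 1.0, 0.95, 0.63 / 0.74),
        t_end=14.0,
        n_points=141,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def preset_lipid(seed: int = DEFAULT_SEED, **overrides) -> SyntheticSpec:
    """Lipid-induced design (20 muM monomer, 100 muM DMPS): 20%/29% rate
    reductions at 0.1/0.2 M eq."""
    kw = dict(
        assay_kind="lipid",
        seed=seed,
        doses=(0.0, 0.05, 0.1, 0.2),
        dose_effects=(1.0, 0.97, 0.80, 0.71),
        t_end=16.0,
        n_points=81,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def preset_binding(seed: int = DEFAULT_SEED, **overrides) -> SyntheticSpec:
    """Depletion binding design: 10 muM preformed fibrils (R_max), Kd 6 muM."""
    kw = dict(assay_kind="binding", seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)


PRESETS = {
    "secondary": preset_secondary,
    "elongation": preset_elongation,
    "elongation-matched": preset_elongation_matched,
    "lipid": preset_lipid,
    "binding": preset_binding,
}
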