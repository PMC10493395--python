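# Methods

## Model and scope

`secflux` analyses four assay geometries of α-synuclein aggregation, all read
out as a fibril-mass proxy (ThT fluorescence or nephelometric scattering)
versus time in hours.

**Seeded secondary nucleation.** With a small seed load (~0.06% preformed
fibrils) and quiescent, mildly acidic conditions, aggregate mass follows the
generalized logistic curve

    M(t)/m_tot = 1 − (1 + (a/c)·e^{κt})^{−c},

where `κ` (h⁻¹) is an effective secondary-process rate, `a` is dimensionless
and carries the primary-process combination `λ = κ√(2a)`, and `c` is a shape
parameter held fixed at 0.3 (corresponding to a secondary-nucleation reaction
order of 4; the reaction order is stored as metadata only and never enters a
computation). Free monomer is `m(t) = m_tot − M(t)` by mass conservation.
Useful exact consequences, all implemented in closed form and covered by
oracle tests (bisection, argmax, quadrature):

- half-time `t½ = (1/κ)·ln[(c/a)(2^{1/c} − 1)]`;
- growth rate at the half-time `dM/dt|_{t½} = m_tot·c·κ·(2^{1/c}−1)·2^{−(c+1)/c}`;
- effective fibril amplification rate `dP/dt = [(1/m_tot)dM/dt|_{t½}]²/(4k₊)`.
  `k₊` is treated as condition-independent (default 1, arbitrary units); it
  cancels in control-relative reporting, which is the only form reported.

**Oligomeric flux.** Secondary nucleation creates oligomers; elongation
(effective rate `r₊`) consumes them. The canonical closed form used is

    φ(t) = m₀·a·κ²·e^{κt} / (2·r₊·(1 + (a/c)e^{κt})²),

with peak time `(1/κ)ln(c/a)`, peak height `m₀κ²c/(8r₊)` and AUC from t = 0
of `m₀κc²/(2r₊(a+c))`. The equivalent form assembled from the curve's
analytic derivatives, `(1/r₊)[(m₀/m)M″ + ((m₀/m)M′)²]`, collapses
algebraically to exactly **twice** this closed form — the two printed
conventions in the literature differ by that factor. We therefore expose both
peak-height conventions (`phi_peak`, `phi_peak_alt = 2·phi_peak`) and note
that every reported quantity is control-normalized, so the convention cancels
identically. `m₀` is taken equal to `m_tot = 1` in normalized units.

**Elongation.** At high seed load (~7–10% fibrils) the early signal is linear
with slope `2k₊P(0)m(0)`; an OLS line over the early window (default: the
prefix of points below 0.3 of the plateau; a fixed-duration window is also
available) estimates it, and slopes are reported relative to the control,
cancelling `P(0)` and `m(0)`.

**Lipid-induced nucleation.** With DMPS vesicles and no seeds, the early
phase obeys `M(t) = C·t²` with
`C = K_M·k_n·k₊·m₀^{n+1}·b/(2(K_M+m₀))`; `K_M = 125 μM`, `n = 2`,
`b = [DMPS]/L = 3.3 μM` are literature-fixed. The printed grouping of these
constants is ambiguous in the sources; the implemented grouping is documented
here, and because only `C` is identifiable from one trace, all reported
quantities are ratios in which the grouping cancels. The implied `k_n·k₊`
product is bookkeeping under this grouping.

**Binding by supernatant depletion.** Bound compound = total −
supernatant (clamped at 0, with a warning beyond 5% excess), fitted by the
standard 4PL dose-response
`R = R_min + L^H(R_max − R_min)/(L^H + K_d^H)`, optionally with `R_max`
pinned to the receptor (fibril) concentration.

## Estimators and numerical choices

- **Generalized logistic fit** (`GeneralizedLogisticModel`): least squares
  over `(log a, log κ)` with `c` fixed; bounds a ∈ [10⁻⁶, 10],
  κ ∈ [10⁻³, 10] h⁻¹; 16 Latin-hypercube starts (seed 20230828) plus one
  data-driven start (half-time crossing and maximum slope) — the landscape is
  benign but not convex. After the best start converges, two unconditional
  Gauss–Newton steps with a central-difference Jacobian pin the optimum to
  ~10⁻¹² (step-acceptance solvers stall ~10⁻⁹ away because the remaining
  improvement is below float64 cost resolution); this is what makes the
  fitted parameters exactly invariant (to <10⁻¹⁰) under affine changes of the
  raw signal such as a fluorophore quench.
- **Amplitude/offset profiling** (`profile_scale`, the pipeline default): the
  fitted model allows `y ≈ s·M(t) + o` with `(s, o)` solved by linear least
  squares at every evaluation. Rationale: windowed normalization pins the
  curve to noisy few-point baseline/plateau means, and with the plateau fixed
  at exactly 1 a 1% amplitude error moves the fitted κ by ≈3.7%. Profiling
  re-estimates that affine freedom from all points; measured per-experiment κ
  scatter drops from 1.26% to 0.92% (Cramér–Rao bound 0.65%) at σ = 0.02,
  and noiseless recovery stays exact. The alternative `window_match` mode
  instead pushes the model curve through the same baseline/plateau window
  transform as the data; plain unnormalized fitting is also available.
- **Flat-trace handling**: a raw trace whose plateau does not exceed its
  baseline by more than 4 standard errors of the window difference raises a
  no-growth signal; a normalized trace whose maximum is below 0.2 of the
  plateau reference is declared `no_aggregation`. Either way no parameters
  are extracted and the condition's relative rates are reported as 0 with a
  complete-inhibition flag (and excluded from significance testing, where its
  variance is degenerate by construction).
- **Normalization**: per-well by default (each well's baseline/plateau window
  means; the op-level defaults are 3 baseline / 5 plateau points), with
  per-experiment normalization of the technical mean as the alternative. The
  pipelines use wider per-assay windows (secondary 15/30, elongation 5/10,
  lipid 8/10) sized from the sensitivity analysis above; per-well normalized
  arrays are averaged before the experiment-mean trace is constructed, so a
  rare single-well noise excursion cannot trip the normalized-range check.
- **Quadratic fit** (`EarlyQuadraticModel`): linear in `C`, solved exactly; a
  basin-hopping route exists and agrees (asserted on random instances). A
  nuisance intercept is fitted by default because baseline noise otherwise
  propagates into `C` as `ΔC = δ·Σt²/Σt⁴` (~4% per experiment at σ = 0.02);
  `fit_intercept=False` restores the pure `C·t²` form. Both are exact on
  noiseless origin-through data.
- **Dose-response fit** (`DoseResponseModel`): `K_d` in log-space (always
  positive), Hill slope initialised at 1 and bounded to [0.05, 20], `K_d`
  initialised at the geometric mean of the ligand range. Residuals are
  divided by the model value by default — the correct weighting for
  concentration measurements with a constant coefficient of variation (LC-MS
  quantification) — and `R_min ≥ 0` because a bound concentration cannot be
  negative; both choices are switchable. At the noisy reference design this
  raises the fraction of K_d estimates within ±15% from 87.5% to 99.5%.
- **Statistics**: ratios versus the control mean; SEM with the n−1
  denominator across experiment-level values (technical replicates are
  averaged first). Many-to-one comparisons use Dunnett's test (all reported
  comparisons are against the vehicle control; Bonferroni-corrected t-tests
  are selectable); significance bands `*` ≤0.05, `**` ≤0.01, `***` ≤0.001,
  `****` ≤0.0001 — the single-star band is included by standard convention
  even though some report styles start at `**`.
- **Overflow policy**: all logistic expressions are evaluated through
  `logaddexp`/softplus so that large `κt` neither overflows nor loses the
  asymptotes (M → m_tot, derivatives → 0). The derivative-assembled flux
  cancels two O(c·u) terms (u = (a/c)e^{κt}), so its float64 error grows like
  `c·u·ε`; consistency checks against the closed form are run in the fitted
  parameter regime (a ≥ 5·10⁻³, c ≥ 0.25) where that assembly is well
  conditioned.

## Synthetic data

The generators emulate the study designs, not the underlying stochastic
chemistry: each condition's normalized mean curve is the fitted forward model
(logistic / clipped line / clipped quadratic / 4PL), converted to raw
fluorescence as `quench × (plateau_scale·M + baseline + plateau_scale·ε)`
with i.i.d. Gaussian ε (σ = 0.02 normalized units by default) and a
dose-proportional quench reaching 23% at the top dose. Replicate structure is
3 experiments × 3 technical replicates. Experiments carry a 3% CV lognormal
jitter of the rate parameter, drawn once per experiment and **shared across
conditions** (a plate-level effect): this makes SEM across experiments
meaningful while keeping control-normalized means unbiased for the programmed
dose factors (the shared factor cancels exactly in the ratio of means).

Default presets program the study's observed effect sizes as ground truth:
κ factors √(1−r) for amplification reductions r = 14/17/37% at
0.02/0.05/0.075 M eq plus a flat complete-inhibition dose at 0.25 M eq
(secondary); slope factors 0.97/0.92/0.74 at 0.05/0.1/0.15 M eq (elongation —
only the top-dose effect is an observed value, the intermediate factors are
generator choices); k_n factors 0.97/0.80/0.71 at 0.05/0.1/0.2 M eq (lipid);
and, for the flux study, matched-dose elongation factors (1.0, 0.95,
0.63/0.74) chosen so the flux-peak reductions are 14% and 26% at 0.02 and
0.075 M eq given the κ factors. Binding: K_d = 6 μM, H = 1, R_max = 10 μM,
8 doses log-spaced 0.5–50 μM, 5% multiplicative noise. Time bases are sized
so every non-flat condition genuinely reaches plateau (60 h secondary, 14 h
elongation, 16 h lipid) — plateau-window normalization is biased otherwise.

What the generators do *not* emulate: stochastic nucleation, drift and
photobleaching, well-position effects, saturating ThT binding, non-Gaussian
outliers, and any dose-dependence of `a` or of the noise. Passing recovery
tests therefore demonstrates that the analysis chain is unbiased and
well-calibrated under its own model assumptions at realistic noise, not that
those assumptions hold for any particular instrument.

Determinism: a fixed seed gives byte-identical output, and a dataset's
manifest (the generating spec plus realized per-experiment parameters)
regenerates it exactly.

## Problem sizes used in validation

The validation suite runs the κ-recovery study on 100 datasets (3×3
replicates each), the dose-response recovery on 200 noisy replicates, the
ANOVA null calibration on 1000 simulated datasets, and the closed-form/oracle
comparisons on 100–1000 random parameter draws; the full-pipeline effect-size
checks use the default presets at a fixed seed. These sizes give simulation
standard errors comfortably below the tolerances being checked.

## Known limitations

- `c` is a fixed configuration constant; no attempt is made to infer the
  secondary reaction order from data, and the printed relation between `c`
  and the reaction order in the source literature is not recoverable.
- Each condition is fitted separately; there is no global multi-curve fitting
  with shared parameters across doses.
- The flux approximation assumes the logistic description holds and `r₊` is
  per-condition constant; no mechanistic oligomer population model
  (conversion/dissociation) is included.
- Absolute `k_n·k₊` values from the lipid module depend on the documented
  constant grouping; only ratios are interpretation-safe.
- Proprietary plate-reader exports must be converted to CSV upstream; only
  the long-form and wide-plate CSV dialects are parsed.
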