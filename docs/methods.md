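# Methods

## Structural models and steady state

Drug input is a zero-order infusion at rate `R0 = dose/T_inf` over `T_inf`
hours, repeated every `τ` hours. Disposition is mammillary with one or two
compartments, parameterised in clearance form: (CL, V) or (CL, V1, Q, V2),
units mg, L, h throughout (concentrations mg/L). For two compartments the
hybrid rate constants α ≥ β > 0 solve
`λ² − (k10 + k12 + k21)λ + k10·k21 = 0` with `k10 = CL/V1`, `k12 = Q/V1`,
`k21 = Q/V2`; the discriminant is written as `(k10 + k12 − k21)² + 4·k12·k21`
to avoid cancellation, and `β` is recomputed as `k10·k21/α` when rounding
drives it non-positive.

Because every single-dose response is a sum of exponentials, the steady-state
profile over one interval is closed-form: each exponential accumulates by
`1/(1 − e^(−λτ))`. During the infusion the profile is the rising term plus the
accumulated tail of all prior doses; afterwards only the accumulated washout
remains. `expm1` keeps `1 − e^(−x)` accurate for small rate–time products.
Time is measured from the start of the most recent infusion; the interval is
the closed set `[0, τ]`, and trough samples drawn shortly before the next
dose map to `t = τ − offset`. Only steady state is exposed publicly — the
study samples after several days of therapy — while non-steady-state
superposition and ODE integration exist as independent test oracles.

Exposure is summarised as `AUC₂₄ = daily dose / CL`, exact for any linear
mammillary model at steady state (mass balance); the test suite confirms it
against fine-grid quadrature to 0.1%. Terminal half-life is `ln2·V/CL` (one
compartment) or `ln2/β`. Note that as Q → 0 the β-phase *coefficient*
vanishes: the profile converges to the one-compartment profile while `ln2/β`
itself diverges, so the strict terminal half-life is not continuous in that
limit — the tests assert profile convergence and the dominant-phase
half-life.

## Individual estimation

Each subject's sparse profile (four points in the default design) is fitted
by weighted least squares, `Σ wᵢ(yᵢ − f(tᵢ))²`. Because the assay error is
proportional to concentration (reported CV below ~5%), the default weights
are `1/f(tᵢ)²` (constant CV about the prediction); `1/yᵢ²` and uniform
weights are configuration options, since fixed data-based versus
prediction-based weighting are both defensible readings of a WLS setup whose
variance model is not estimated. Predictions are floored at 1e−9 mg/L before
inverse weighting (with a warning) to keep the objective finite.

Positivity is enforced by optimising in log-parameter space. Robustness on
four-point data comes from a fixed multistart grid (CL ∈ {1, 2, 4, 8} L/h ×
V ∈ {10, 30, 90} L, with Q = CL/2 and V2 = 2·V1 as the two-compartment
analogues). The minimiser is Levenberg–Marquardt on the weighted residual
vector with an explicit forward-difference Jacobian evaluated in one batched
array pass; a derivative-free Nelder–Mead fallback is available by
configuration. To keep cohort-scale experiments tractable the grid is
traversed as screen → coarse → polish: all starts are ranked by one batched
objective evaluation, the best few get a short LM run, and the two best
coarse optima are polished to the configured tolerance (1e−12 relative by
default). The procedure is deterministic — identical data and configuration
give bit-identical results — and recovers noiseless parameters to near
machine precision.

Goodness of fit is reported as the squared Pearson correlation between
observed and model-predicted concentrations. This is an interpretation
choice (regression-through-origin R² is the main alternative); it is
undefined, and raises, when either vector has zero variance. Identifiability
requires at least as many points as parameters (2 or 4); anything less
raises rather than returning a degenerate fit. With four points a
two-compartment model can interpolate exactly, so its clearance estimate is
more variable than the one-compartment one — mirroring how sparse designs
behave in practice — and both orders are always fitted so each population
model can be compared at its own structural order.

## Population models and conditioning

A registry entry carries the structural order, a typical clearance, a
between-subject SD of clearance, and an optional covariate equation:
constant, linear proportional scaling about a reference covariate value,
power-law scaling, or a saturating form `CL_max·x/(x50 + x)`. Conditioning
yields `AUC_pred = daily dose / CL_typ(patient)` and a 68% interval from
`CL_typ ± SD` (lower AUC bound from CL + SD). For the saturating form the
dispersion is attached to the maximum-clearance parameter, so the interval
is built by shifting CL_max by ±SD and re-evaluating the equation.
Creatinine clearance comes from Cockcroft–Gault,
`(140 − age)·weight/(72·Scr)` × 0.85 for females, with serum creatinine in
mg/dL (µmol/L inputs are divided by 88.4).

The shipped registry reproduces the published structure of the five models
(Sandri two-compartment/body weight; Manchandani and Kubin
one-compartment/no covariate; Avedissian two-compartment/creatinine
clearance with dispersion on CL_max; Miglis two-compartment/no covariate)
and places the covariate-free typical clearances at the published set
{2.4, 2.5, 2.6} L/h — the assignment of those three values to the three
models, the dispersion values (50% of typical CL), and both covariate
equations are synthetic placeholders, flagged in the registry file name and
per-entry provenance strings, because the source publications' exact values
are not bundled. Every number is editable through the JSON registry, whose
round-trip is bit-exact.

## Evaluation

Per subject: % bias `(pred − obs)·100/obs`, % precision `|bias|`. Per model:
arithmetic means of both (so a small mean bias can coexist with large mean
precision), squared Pearson correlation of observed vs predicted AUC, and
coverage = share of subjects whose observed AUC lies inside the 68% interval,
boundaries inclusive (a tie counts as captured). Pairing is strict: a model
is only ever compared against individual fits of its own structural order,
and the evaluation raises, naming the subjects, when such fits are missing.

## Synthetic cohort

The generator reproduces the study conditions: age 51.5 ± 13.4 y (≥ 21),
weight 69.7 ± 20.2 kg (35–140), CrCL 84 ± 47 mL/min (> 5), 12/13 male. All
demographic draws are truncated normals whose *location* is recentred so the
truncated mean equals the target — physiological truncation otherwise shifts
the weight mean by about +2 kg and CrCL by about +5 mL/min. CrCL is drawn
first and serum creatinine back-solved through Cockcroft–Gault, because CrCL
is what covariate models consume and its cohort moments are what is known;
the inversion makes re-derived CrCL reproduce the drawn value exactly.

Dosing: 50/75/100 mg per administration every 12 h, the strength sampled
uniformly among those putting the daily dose in 1.7–3.0 mg/kg (nearest
feasible strength for weights where none qualifies), infusion duration
uniform on 0.5–4 h. Four sample times per the study windows: within 0.5 h of
the next dose; 0.5–1 h after the end of infusion; 3–8 h after the end of
infusion (clipped at the interval end); within 4 h of the next dose.
Observations get proportional noise `y = C·(1 + ε)`, `ε ~ N(0, 0.05²)`,
redrawn if non-positive.

True parameters default to a one-compartment truth with V log-normal
(median 25 L, CV 30%) and CL log-normal, median 2.5 L/h, CV 65%, drawn
independently of weight and CrCL (null covariate effect; a weight-coupled
mode `cl_weight_power` and a normal-on-CL mode exist for calibration
experiments). The CL dispersion deserves comment, because no generative
variances are reported for this population and the choice is consequential.
The median gives a median terminal half-life of ln2·25/2.5 ≈ 6.9 h, matching
the reported 6.8 h. The CV is set deliberately wide: observed and predicted
AUC share the daily-dose factor, so for a covariate-free model the
population obs-vs-pred correlation is approximately
`r² = 1/(1 + (e^(σ²) − 1)(1 + 1/CV_dose²))` with σ the log-SD of CL — with
the dose spread this design produces, σ ≈ 0.6 (CV ≈ 65%) is required for
r² to sit robustly below 0.2 at n = 200. That is the regime the package is
designed to reproduce — substantial unexplained clearance variability — and
it makes the simulated half-life span somewhat wider than a 13-patient
sample would show. Consequences to keep in mind when reading test output:
simulated coverage of the placeholder intervals (~55–65%) sits below the
>75% a better-matched dispersion would give, and passing tests demonstrate
the pipeline's behaviour under *these* generative assumptions, not the
field-accuracy of any published model.

## Problem sizes and numerical choices

The cohort experiments use n = 200 subjects (50 seeded replicates for the
correlation-replication property, where the binding quantity is the share of
replicates with every model's r² below 0.2), n = 5000 for moment and
coverage-calibration checks, and n = 13 for study-sized smoke tests — sizes
chosen so each experiment's sampling noise is small relative to the margin
it asserts. All randomness flows through a single seeded generator per run;
the CLI records the seed and a configuration hash in a manifest. CSV output
uses six significant digits, which round-trips every pipeline decision.
Degenerate inputs raise typed errors rather than returning sentinel values:
times outside `[0, τ]`, non-positive parameters, empty sampling windows
(infusions ending within ~1 h of the next dose), zero-variance r², intervals
with SD ≥ CL, and pairing across structural orders.

## Known limitations

- Individual estimation is WLS only; no MAP-Bayesian estimation and no
  standard errors on individual parameters.
- Registry numbers are placeholders (structure is faithful); quantitative
  conclusions about the five published models require transcribing their
  source values.
- The generator draws true clearance independent of covariates by default;
  it does not simulate nephrotoxicity, MIC distributions, or PK/PD indices,
  and its between-subject variability is a stand-in calibrated as described
  above, not an estimate from patient data.
- Only steady-state, fixed-interval regimens are supported; no absorption
  models, nonlinear elimination, or time-varying clearance.
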