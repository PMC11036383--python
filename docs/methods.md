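# Methods

`isowash` simulates the isolation of a crystallized active pharmaceutical
ingredient (API) by dead-end pressure filtration followed by cake
washing, and provides the calibration and design-space tools that turn
the simulator into a process-development aid. This note records the
models, their assumptions, the parameters that matter, and the places
where the design was genuinely open.

## Filtration model

A batch suspension (dry solid mass, saturated mother liquor of known
composition) is filtered at constant driving pressure ΔP on a filter of
area A and medium resistance Rm. The cake resistance per unit dry solid
mass comes from Carman–Kozeny theory,

    α = 180 (1 − ε) / (ρs ψ² x² ε³)        [m/kg],

with cake porosity ε, particle sphericity ψ, mean particle size x
(volume-weighted mean, in metres) and crystal density ρs. Compressible
cakes scale the resistance with a power law,

    α(ΔP) = α_ref (ΔP / ΔP_ref)^n,

where n is the compressibility index (n < 1 low/moderately compressible,
n > 1 highly compressible; the high/extreme border is fuzzy in the
literature and the band threshold is configurable). The reference
pressure defaults to 1 bar; no reference pressure is standard, so it is
an explicit, configurable model constant.

At constant pressure the filtrate volume obeys

    dV/dt = ΔP A² / (μ (α w V + Rm A)),
    t(V)  = (μ / (A ΔP)) (α w V² / 2A + Rm V),

with μ the liquor viscosity and w the dry solids deposited per unit
filtrate volume. Because ΔP is constant the compressibility scaling is a
constant factor and the quadratic closed form is exact, so the simulator
evaluates it directly instead of integrating an ODE — there is no
discretization error to control, and the "analytic oracle" test is an
identity check on an independent re-derivation.

Filtration stops at **dryland**: the free liquid above the cake is
exhausted and the cake pores remain exactly saturated with mother
liquor. The dryland filtrate volume is the suspension liquor volume
minus the cake void volume ε/(1−ε)·(solid mass/ρs); this fixes w
self-consistently (all solids are assumed to deposit — no fines
passage, no dissolution). Suspension settling before or during
filtration is not modelled (the suspension is treated as uniform until
deposited). The stated end point is algebraic, so no event-detection
tolerance is needed.

Two data-reduction fits mirror standard lab practice: `darcy_fit`
regresses t/V on V (slope → α, intercept → Rm) and reports negative
intercepts verbatim with a warning flag — negative fitted medium
resistances arise from cake pre-settling on the medium and are
physically meaningless for forward simulation, which rejects Rm < 0.
`fit_compressibility` regresses ln α on ln ΔP; with a single distinct
pressure the slope is unidentifiable and the fit pins n = 0 with a flag.

## Washing model

Washing starts from the saturated dryland cake: one void volume V0 of
mother liquor carrying dissolved API and impurities. The wash ratio W is
wash volume per void volume. The solid phase is immutable throughout
(no dissolution or growth — a stated model assumption; the anti-solvent
first-wash blends in the fixtures exist precisely because real systems
violate it). Three mechanisms are provided:

* **Displacement** (ideal piston): the first min(W, 1) pore volumes of
  filtrate are pure mother liquor, any excess is pure wash liquid;
  residual mother-liquor fraction max(0, 1 − W).
* **Axial dispersion**: one-dimensional convection–dispersion washout of
  a uniformly saturated cake at Peclet number Pe (convective/dispersive
  transport ratio). The exit concentration is the washing complement of
  the classic breakthrough solution,

      c/c0 = ½ [ erfc((W−1)√(Pe/4W)) − e^Pe erfc((W+1)√(Pe/4W)) ].

  This form was chosen over the superficially similar plus-sign
  (resident-concentration) variant because it conserves solute exactly:
  its integral over all W is one pore volume of solute, whereas the
  plus-sign variant integrates to 1 + 2/Pe and leaks 20% of the solute
  at Pe = 10. It reproduces the three washing-curve stages (constant
  rate, intermediate, diffusion tail) and collapses to the displacement
  step as Pe → ∞. The e^Pe term is evaluated as
  erfcx(z)·exp(−Pe(W−1)²/4W), which never overflows. No measured Pe is
  available for the case studies; the per-stage default is 10, a
  mid-range value giving a clearly three-stage curve, and it should be
  treated as a scenario parameter, not a constant of nature.
* **Well-mixed** (MSMPR-style surrogate for strong dispersion), two
  modes. *Feed-and-bleed*: constant hold-up CSTR washout, residual
  solute fraction e^(−W); exactly split-invariant — any partition of a
  total W gives the same final purity, which is the mechanism behind the
  design-space finding that one large wash and several small washes tie.
  *Accumulate*: semibatch charge with no outflow during the aliquot;
  the aliquot dilutes the held liquor, c = c0·V0/(V0+Vw). Between
  consecutive accumulate stages the excess above pore saturation drains
  through (it is recorded as the next stage's filtrate), so an n-stage
  program follows the dilution product Π V0/(V0+Vi) and is strictly
  split-sensitive; the final stage's excess stays held, which
  over-predicts retained liquid by construction — the known bias of the
  semibatch hold-up description.

Species bookkeeping is volumetric with volume-conserving mixing: pores
stay saturated under the outflow mechanisms, retained wash liquid mixes
uniformly into the pore liquor, and each stage closes every species mass
balance to 1e−8 relative by construction (tested across all fixtures and
mechanisms). Back-mixing between a charged aliquot and free liquid above
the cake is not modelled; wash "times" are reporting metadata (the
mechanisms are volume-driven). Cake de-saturation (deliquoring), channel
flow and drying are out of scope.

Washing curves report exit (or, for accumulate, held) concentration per
tracked species, normalized by the initial mother-liquor concentration;
stage segmentation labels points with c/c0 ≥ 0.95 constant-rate and
c/c0 ≤ 0.05 diffusion (thresholds configurable).

## Parameter estimation

`EstimationProblem` is a model object in the statsmodels idiom: it holds
experiments (scenario + observed V(t) series), free parameters among
(ψ, ε, Rm, n), bounds and initial guesses; `.fit()` returns an
`EstimationResult` with estimates, objective, residuals, convergence and
identifiability flags, and a `summary()` table. The objective is
normalized least squares, Σ((V_sim − V_obs)/max|V_obs|)², minimized by
bounded trust-region least squares (`scipy.optimize.least_squares`),
with Rm optimized in log10 space; optional seeded multi-start. This is
deliberately not a maximum-likelihood objective, so objective values are
not comparable with other estimation tools even where the parameter
estimates are.

One subtlety is worth recording: the pre-dryland volume series alone
cannot identify porosity from below — any cake with matching Darcy
curvature and a *larger* dryland volume fits the observed samples
exactly. The information that filtration *stopped* (the last sample is
the dryland endpoint) removes the degeneracy, so the problem adds a
dryland-volume residual by default (`dryland_endpoint=True`; disable it
for series truncated before dryland). The compressibility index is
identifiable only across ≥ 2 driving pressures; single-pressure
problems pin n = 0 with a flag, mirroring the zero-compressibility rows
of single-pressure calibrations. Noise-free two-pressure synthetic
designs recover all four parameters to ≪ 1%; under 1% multiplicative
volume noise the median sphericity error is a few percent (50-replicate
study in the test suite).

## Design space and wash-plan optimization

Sweeps are plain full-factorial evaluations of the filtration + washing
pipeline over grids of wash volumes, stage counts or Pe; responses are
final-cake impurity concentrations in kg per m³ of cake liquor (volume-
based, so the feed-and-bleed response to a single wash of volume Vw is
exactly c0·e^(−Vw/V0)). Failed grid points are recorded with NaN and a
diagnostic; sweeps are deterministic and bit-reproducible.

The **knee** of a wash-volume sweep operationalizes "no meaningful
further impurity removal": the marginal reduction per mL on each grid
interval is compared with the first interval's rate (measured from the
unwashed cake as baseline), and the knee is the left endpoint of the
first interval falling below 5% of the initial rate (threshold
configurable). On an exponential response c0·e^(−V/V*) this converges to
V*·ln 20 ≈ 3 V* as the grid refines — which is why the knee lands near
three cake void volumes for both case studies.

`optimize_wash_plan` enumerates per-stage volumes on a budget grid over
1–3 stages exhaustively (responses are cheap and landscapes tie, so
gradient methods buy nothing); ties are broken toward fewer stages, then
front-loaded plans. For feed-and-bleed all splits tie and the single
wash is returned; for accumulate mode equal splits win.

## Scenarios, physical properties and the synthetic-data generators

Eighteen fixtures transcribe two published case studies: mefenamic acid
(MFA, 27 mm filter, 4.34 g solids in 43.4 g liquor) and paracetamol
(PCM, 24 mm filter, 65 g batch at the per-experiment solid load of
15–25% w/w), each with its crystallization/wash solvent pair, driving
pressure, wash ratio and stage count, the calibrated cake parameters
(ψ, ε, Rm, n) for its solvent pair, and a first-wash blend of
crystallization and wash solvents chosen to suppress anti-solvent
precipitation (10:90 v/v for MFA; the screening-map fractions for PCM).
The diglyme–water crystallization liquor is carried as a single
pseudo-solvent at its fixed 89:11 weight ratio, since no model resolves
the two components. The PCM particle mean size is the case study's
calibrated 61 μm for both powder grades; grade percentiles are retained
as metadata. One printed MFA composition column closes to 1.001 and is
renormalized on ingestion (tolerance 2e−3); all emitted compositions
close to 1e−9.

The case studies publish no solvent or solid physical properties, so a
literature table at 25 °C ships with the package (densities in kg/m³,
viscosities in Pa·s; e.g. heptane 679.5 / 3.86e−4, diglyme–water blend
948.7 / 9.78e−4, MFA crystal density 1260, PCM 1293). Dissolved solids
get melt-like liquid densities equal to their crystal densities and a
nominal 5 mPa·s viscosity contribution; they are minority components, so
liquor properties are dominated by the measured solvent values. Every
value is overridable per scenario. Mixture rules are mass-weighted
specific volumes for density and log-linear (Arrhenius) mixing for
viscosity — simple, monotone, exact for pure components. Absolute
retained-mass predictions inherit the uncertainty of these assumed
properties, which is why the retained-solvent check carries a ±20% band;
temperature-dependent correlations and solubility prediction are out of
scope.

The synthetic generators emulate what a lab series looks like —
a V(t) grid with multiplicative Gaussian noise, and per-stage wash
filtrate compositions perturbed and renormalized — reproducibly from
(scenario, noise level, seed). They do not emulate operator effects that
dominate real discrepancies (late valve closing at dryland, pre-settled
cake, back-mixing above the cake), so passing recovery tests shows the
estimation machinery is correct and well-conditioned, not that real
experimental series are this clean.

## Problem sizes and numerical choices

Default grids are small because the models are closed-form: 200-point
filtration series, 40-point (1 mL) sweep grids, 50-point synthetic
observations, 50-replicate noise studies, 12-replicate noise-monotonicity
studies, 20-step optimization budgets. Dispersion stage integrals use
adaptive quadrature split at the W = 1 breakthrough. Optimizer
tolerances are 1e−12 (xtol/ftol/gtol) — tight because residuals are
cheap. Degenerate inputs are first-class: zero-solids suspensions give
pure-medium Darcy flow, zero-volume washes are identities, flat sweeps
return a degenerate-knee flag.

## Known limitations

* Dryland detection, and therefore retained liquor, is exactly as good
  as the porosity estimate; no partial de-saturation is modelled.
* The PCM two-dose filling protocol of the continuous rig is
  approximated as a single batch with the per-experiment solid load
  applied to one 65 g dose; sequential two-layer cakes are not modelled,
  so PCM filtrate-mass end points are indicative only.
* Dispersion washing treats each stage as starting from a uniformly
  mixed saturated cake; front structure does not persist across stages.
* The accumulate mode's growing hold-up intentionally reproduces the
  semibatch over-prediction of retained liquid; it is a description of
  that operating mode, not of a drained cake.
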