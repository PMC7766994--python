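# Methods

## Model

Quality loss of a frozen product is tracked through scalar indices: CIELab
lightness *L* (dimensionless, falls as flesh darkens), total volatile basic
nitrogen (TVBN, mg N/100 g, rises with protein degradation), panel sensory
scores (taste, overall acceptability; 1–9 scale, 9 best, 5 the acceptability
threshold, falls) and total viable count (TVC, log CFU/g, expected flat in
frozen storage).

**Primary kinetics.** Within one constant storage temperature each index
follows an apparent rate law without mechanistic claim:

- zero order: y(t) = y0 ∓ k·t (L-value, sensory scores),
- first order: y(t) = y0·e^(±k·t) (TVBN),

with k ≥ 0 a magnitude and the sign fixed per index (declared in
`INDEX_DIRECTIONS`, not inferred from noisy slopes). Fitting is ordinary least
squares of y (zero order) or ln y (first order) on time; R² is reported on the
fitted scale. The ln-linearisation is deliberate — it reproduces the standard
two-step workflow of the field and keeps the estimator linear — rather than
nonlinear least squares on the raw scale. Replicates at one sampling time are
averaged before fitting; the replicate SE is kept for plotting only.
Constant series are special-cased to k = 0, R² = 0. Sensory predictions are
*not* clamped during fitting; the [1, 9] floor/ceiling applies only when
simulating forward.

**Secondary (Arrhenius) model.** Rate constants across temperatures obey
ln k = ln k_ref − (Ea/R)(1/T − 1/T_ref), R = 8.314 J/(mol·K), T in kelvin
(°C + 273.15). The regression uses the predictor x = 1/T_ref − 1/T so the
intercept is ln k_ref directly and the slope is +Ea/R. T_ref defaults to
−18 °C, the nominal frozen-chain temperature, putting k_ref on the scale users
care about; `with_reference()` re-expresses a model at any other reference
without changing the temperature dependence. The 95% CI on Ea uses Student-t
with n − 2 degrees of freedom (the df convention is a choice; with the typical
n = 4 temperatures the interval is wide, which is honest). Two indices are
considered to have *similar temperature dependence* when their activation
energies agree within ±20 kJ/mol — the window within which one index (or a TTI
label) can act as a kinetic monitor for another.

## Dynamic prediction

Storage histories are piecewise-constant `TemperatureProfile`s (time unit:
days). Two prediction routes are exposed:

- **Method #1 (effective temperature).** k_eff(t) = Σ_i k(T_i)·t_i / t over
  the profile truncated at t (partial steps prorated); T_eff is the Arrhenius
  inversion of k_eff and is reported alongside the prediction. The predicted
  value is the closed-form isothermal solution at k_eff.
- **Method #2 (stepwise integration).** The trajectory is marched step by
  step, applying the exact linear/exponential update within each
  constant-temperature increment.

Because the per-increment updates are exact, the two methods coincide (to
float rounding, asserted at 1e−9 relative) on every piecewise-constant
profile, and both are invariant to step permutation (memoryless kinetics).
No separate explicit-Euler integrator exists: it would be bit-identical on
step profiles, since the first-order update is itself exponential. Δt
sensitivity enters only through `discretize()`, which converts a logger trace
to a step profile by zero-order hold (left-endpoint temperatures — data-logger
semantics; the choice of endpoint is a convention). `predict_method2` accepts
a `dt` that subdivides steps; tests assert it is inert.

Forward simulations clamp to physical ranges: sensory at ≥1, L-value at ≥0,
TVBN unbounded. Clamping is applied to reported values, not to the marching
state, preserving the Method #1 ≡ Method #2 identity.

## Shelf life and cold-chain scenarios

Shelf life at constant T is span/k(T), where the span is |y0 − limit| (zero
order) or |ln(limit/y0)| (first order); k = 0 signals an infinite shelf life
(`math.inf`). Remaining shelf life (RSL) converts a *current* value to days
left at a reference temperature; values past the limit give 0 with a warning.
At constant temperature elapsed + RSL = SL exactly (tested).

`run_scenario` treats each profile step as a distribution stage: the stage-end
value comes from Method #1 (chosen over Method #2 for scenario reporting for
its simplicity — over the narrow frozen range the two are equivalent on step
profiles anyway), the reported T_eff is cumulative from time zero, and the RSL
is evaluated at the scenario's reference temperature (default −15 °C). The
built-in `distribution150` preset is a 150-day chain — 25 d packing plant at
−15.6 °C, 25 d transport at −13.3 °C, 50 d retail at −11.8 °C, 50 d domestic
at −10.4 °C — with each stage represented by its per-stage effective
temperature as a constant step. `nominal_rsl` gives the history-blind "use-by"
arithmetic (SL at the declared storage temperature minus elapsed time) for
comparison.

## Validation metrics

Af = 10^(mean |log10(pred/obs)|) ≥ 1 and Bf = 10^(mean log10(pred/obs)) > 0;
base-10 logarithms follow the predictive-microbiology convention (paired 10^
and log10, any base cancels). Perfect agreement gives (1, 1); Af ≥ max(Bf,
1/Bf) always; swapping predicted and observed inverts Bf and leaves Af
unchanged. The per-observation relative error RE = (obs − pred)/pred is
screened against the open interval (−0.3, 0.15) — strict inequalities, so
RE = 0.15 is *outside* — and Bf against fail-safe (< 0.7) / fail-dangerous
(> 1.15) boundaries, inclusive on the acceptable side.

## Synthetic data generator

The generator emulates a frozen-fish storage study for three products
(sea bream, sea bass, tuna). Presets are anchored to the products' published
isothermal characterization:

- TVBN: y0 = 6.8 / 8.4 / 7.6 mg N/100 g and limits 15 / 20 / 22 for
  bream/bass/tuna; rate constants k_i = ln(limit/y0)/SL_i from the four
  shelf lives at −5/−8/−12/−15 °C; Ea refit from those anchors (the published
  Ea table is inconsistent with the tuna shelf-life row — the refit keeps the
  preset self-consistent).
- Overall acceptability: zero order, 9 → 5, k_i = 4/SL_i, Ea refit likewise.
- Taste: shares the acceptability timescale (panel scores move together) with
  its own published Ea.
- L-value: initial 66.7 / 56.3 / 71.7; no numeric rate is published, so the
  preset is a **synthetic stand-in**: a figure-scale decline of ~10 L-units
  over the sensory shelf life, with the published per-product Ea.
- TVC: flat at 4.4 / 5.5 / 3.5 log CFU/g.

Design defaults mirror the study: temperatures −5/−8/−12/−15 °C, 8 evenly
spaced sampling points (5–10 in the study) per condition over that condition's
own shelf life capped at 420 d (the 14-month span), triplicate replicates.
Noise is additive i.i.d. Gaussian on the measurement scale with SDs L 1.5,
TVBN 0.8, sensory 0.4, TVC 0.2 — stand-ins chosen to match the error-bar scale
of replicate SEs, since true replicate noise is only depicted graphically in
the source study. TVBN noise is additive (not log-normal) because the reported
errors are replicate SEs on the raw scale. Sensory observations are rounded to
the 0.5 panel granularity and clamped to [1, 9] *before* replicate averaging;
consequently zero-noise "exact recovery" checks use non-sensory indices.
Datasets are regenerable bit-identically from (preset, design, seed) via
`numpy.random.default_rng`.

What passing tests show — and don't. The generator has i.i.d. noise, no
panelist random effects, no autocorrelated logger noise, no batch effects, and
its trajectories are exactly the model family being fitted. Parameter-recovery
and CI-coverage results therefore validate the estimation machinery, not the
adequacy of apparent zero/first-order kinetics for any real product.

## Numerical and statistical choices

- Internal time unit days (hour inputs converted exactly, 24 h = 1 d); kelvin
  inside all kinetic math, °C at every interface.
- CI coverage of the full synthetic loop (generate → primary fits → Arrhenius
  CI) was checked with a 1,000-replicate study at a reduced design (5 points
  per temperature): empirical coverage ≈ 95%, i.e. treating the fitted ln k
  values as homoskedastic regression inputs is adequate at this design because
  each temperature is sampled over its own shelf-life horizon, equalising the
  relative precision of the k̂.
- At the default design the median relative error of the recovered Ea is
  ≈ 4–5%; the k_ref error at −18 °C is slightly larger because the reference
  sits outside the −5…−15 °C data range.
- Order selection by comparing R² (zero vs first, ties to zero) discriminates
  weakly when the curvature over the observed span is mild: for TVBN rising
  6.8 → 15 at the default noise it picks first order in only ~70% of
  replicates. Declaring the order per index (as the presets do) is the
  recommended practice; automatic selection is provided for exploration.
- Af/Bf sanity bands on synthetic dynamic data follow analytically from the
  noise model (E[Af] ≈ 10^(σ_log·√(2/π))): ≤1.03 for L-value but ≤1.10 for
  TVBN, whose relative noise is the largest. A blanket "Af ≤ 1.02" is not
  attainable for TVBN at the stated noise.
- The Var abuse preset (−12 °C/1 d, −5 °C/1.5 d, −8 °C/1 d per cycle) starts
  at the −12 °C step; its T_eff from the Arrhenius machinery is ≈ −7.5 °C for
  Ea ≈ 66 kJ/mol — warmer than the time-weighted mean −7.86 °C, as the
  exponential averaging overweights warm excursions. Summary statements that
  equate T_eff with the arithmetic mean temperature understate abuse.

## Limitations

- Kinetics are memoryless Arrhenius: no phase-change corrections near the
  freezing point, no history-dependent mechanisms, no microbial growth models
  (TVC is only slope-tested).
- The distribution-chain preset represents each stage by a constant effective
  temperature, not a fluctuating trace; within-stage excursions are averaged
  away by construction.
- Secondary models extrapolated beyond the fitted −5…−15 °C range (e.g. to
  −18 °C) inherit the usual extrapolation risk; the package reports CIs so the
  user can see it.
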