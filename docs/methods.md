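# Methods

This note documents the models implemented in `acclim`, the calibration of
the synthetic-data generator, and the numerical and design choices made where
the underlying protocols admit more than one reasonable reading.

## Respirometry model

Closed-phase intermittent-flow respirometry measures the decline of dissolved
oxygen while the flush pump is off. The package models the concentration as

    O2(t) = C0 − (MO2 / ((V − Vm)·60) + s_b)·t + ε,   ε ~ N(0, σ_trace²)

with `MO2` the whole-animal oxygen consumption (mg O₂ h⁻¹), `V` the chamber
volume (1.1 l default), `Vm` the fish volume, `s_b` the bacterial background
decline (mg l⁻¹ min⁻¹) and t in minutes. Reduction inverts this exactly:
an ordinary least-squares line gives the decline rate, the blank rate
estimated from a no-fish trace in the same chamber on the same day is
subtracted on the concentration scale, and

    MO2 = (decline − blank) · (V − Vm) · 60.

Fish volume is computed from body mass assuming tissue density 1.0 g ml⁻¹
(configurable); the protocols this emulates use `Vm` without stating how it
was measured, and neutral buoyancy is the standard field assumption.

Routine metabolic rate (RMR) is the arithmetic mean of the three consecutive
closed-phase estimates taken after overnight habituation; a count other than
three is flagged, not rejected. Negative fitted declines (oxygen rising) are
likewise flagged rather than clamped so the inference layer sees unbiased
values; blank-rate estimates, by contrast, are floored at zero because
bacterial respiration cannot add oxygen.

## Maximal metabolic rate and recovery

After an exhaustive chase (mean 4.75 min) the fish re-enters the chamber
(~12 s transfer) and eight 5-minute MO₂ windows alternate with 5-minute
flushes, spanning exactly 75 minutes; window midpoints fall at 2.5, 12.5, …,
72.5 min. Post-exercise oxygen consumption is modelled and fitted as

    MO2(t) = β0 + β1·ln t,   β1 ≤ 0, t = minutes since re-entry.

The maximal metabolic rate is the fitted curve read at `eval_time`. The
curve diverges at t = 0, so "the intercept" is operationalised as the value
at t = 1 min (where ln t = 0) — consistent with "immediately after
exhaustion" while staying well-defined. `eval_time` is configurable (e.g.
0.25 min to extrapolate to the transfer moment) and recorded in the output;
the natural-log base only rescales β1 and leaves the t = 1 value unchanged.
The generator floors simulated recovery values at the fish's routine rate so
late windows never undershoot rest. A no-back-extrapolation alternative
(`mmr_peak`, the highest observed window, earliest window on ties) is
reported alongside. Aerobic scope is MMR − RMR exactly, and β1 is the
recovery-rate statistic passed to inference. Recovery windows are modelled
directly on the MO₂ scale, i.e. as already background-corrected
measurements; blanks are estimated and subtracted only in the closed-phase
RMR reduction.

## Thermal tolerance

Thermal-challenge tanks ramp at a constant 0.17 °C min⁻¹ from the group's
acclimation temperature; the ramp is treated as exactly linear (the physical
balancing of hot and ambient inflow is not modelled). The critical thermal
maximum is the ramp temperature at loss of equilibrium, accepted either as an
elapsed time (converted through the ramp) or as a recorded temperature
(passed through); the two representations agree to rounding. CTmax is kept
per fish — trial-level aggregation is left to the inference layer so that
tanks never silently become the unit of analysis.

## Inference layer

All factorial models are ordinary least squares on
`response ~ covariate + population + temperature + population:temperature`.

* **Sums of squares** are sequential (Type I) with the mass covariate entered
  first, then population, then acclimation temperature, then the interaction
  — the default behaviour of the classical ANOVA workflow this mirrors. The
  sequential table is built by explicit nested-model comparison because the
  formula machinery orders numeric terms after categorical ones. A partial
  (Type III, sum-to-zero contrasts) option is provided; on these nearly
  balanced designs the two are nearly identical.
* **Transforms.** Metabolic rates, body mass and condition factor are
  log₁₀-transformed. Whenever the response is log₁₀, the covariate enters as
  log₁₀(mass), which makes the common fitted slope the allometric mass
  exponent; the recovery-rate slope (a signed quantity) is analysed on the
  raw scale with raw mass as covariate.
* **Adjusted means** are model predictions at mass = 108.6 g (the overall
  cohort mean; configurable), averaging the interaction cells of the other
  factor with equal weight. SEMs come from the coefficient covariance;
  back-transformed means (the default reporting scale for rates) carry
  delta-method SEMs, `SEM_bt = ln 10 · mean_bt · SEM_log`. Predictions at a
  reference mass outside the observed range warn.
* **Homogeneity of regression slopes** is an extra-sum-of-squares F test of
  the covariate × factor (and covariate × interaction) terms added to the
  common-slope model. Its type-I rate is verified by Monte Carlo in the test
  suite (200 seeds, nominal 0.05).
* **Tukey HSD** is computed on the (adjusted) least-squares means with the
  studentized-range distribution at the model's residual df; the standard
  error of each pairwise contrast comes from the coefficient covariance,
  which reduces to the Tukey–Kramer form under imbalance. With two groups
  the adjusted p equals the pooled-variance t-test p (q = t·√2). Pairwise
  tests are reported only after a significant omnibus F for that factor
  (α = 0.05).
* **Condition factor** is Fulton's `K = 100·M/L³` (M in g, L in cm).

## Generator calibration

Defaults describe a 4-population × 4-temperature (8, 11, 15, 19 °C) design:
158 respirometry fish (two cells of 9, fourteen of 10) and 160
thermal-challenge fish (10 per cell). Cell mass and condition-factor targets
follow the two cohort tables of the emulated study (respirometry fish
~85–120 g; challenge fish ~35–60 g, with the 19 °C groups lighter and
plumper). Fork length inverts the condition factor, `L = (100·M/K)^(1/3)`.

Anchored quantities (whole-animal rates for a 108.6 g fish, mg O₂ h⁻¹):

| acclimation | CTmax mean (°C) | RMR ref | MMR ref | recovery β1 |
|---|---|---|---|---|
| 8 °C | 26.1 | 5.257 | 35.0 | −3.8 |
| 11 °C | 26.6 | 8.2 | 38.5 | −4.0 |
| 15 °C | 28.1 | 12.3 | 42.0 | −4.4 |
| 19 °C | 28.9 | 13.4 | 34.0 | −2.6 |

The 8 and 19 °C CTmax anchors sit mid-way in the reported 26.0–26.2 and
28.7–29.1 °C population bands; 26.6 and 28.1 °C place the largest acclimation
step (~1.5 °C) between 11 and 15 °C. The 8 °C RMR equals the mass-specific
anchor 48.41 mg O₂ kg⁻¹ h⁻¹ × 0.1086 kg; the ladder rises roughly 2.5–3-fold
to 19 °C with the 15 and 19 °C rungs statistically indistinguishable. MMR
peaks at 15 °C and declines above it, so scope collapses at 19 °C; the 19 °C
recovery slope is smallest in magnitude (slowest repayment of the oxygen
debt). RMR scales with mass^1.12 and MMR with mass^0.82; the scope allometry
is emergent (scope = MMR − RMR per fish), since three exponents cannot be
imposed simultaneously. Population effects default to zero for every trait —
the design emulated found none for CTmax and RMR, and the modest
population differences it reported for MMR/scope are not baked in.

Dispersion defaults are inferred, not quoted (the emulated study reports only
SEMs of adjusted means): between-fish CV 8% for RMR and MMR, CTmax SD 0.5 °C,
body-mass CV 12%, condition-factor SD 0.04, trace noise 0.005 mg l⁻¹,
background decline 0.002 mg l⁻¹ min⁻¹, recovery-window CV 5%. They were
chosen once so that group-level standard errors are of the magnitude typical
for n = 10 cells in such studies, and are all configurable.

What the generator does *not* emulate: probe drift and flush-phase mixing
dynamics, diurnal or digestion-driven metabolic variation, tank hydraulics,
growth over the trial period, family structure within populations, and any
true population × temperature interaction. Passing tests therefore
demonstrate that the pipeline's estimators are unbiased and correctly
calibrated for data that satisfy the stated models — not that real traces
are free of the artefacts the generator omits.

## Problem sizes and determinism

Monte-Carlo tests use 20 replicate studies (200 for the type-I calibration of
the slopes test), sizes at which the checked quantities have standard errors
comfortably below the asserted tolerances. All stochastic tests and the
acceptance script derive their seeds explicitly; identical configuration and
seed reproduce every table byte for byte. `scripts/acceptance.py` averages
its reported quantities over 20 replicate simulations seeded from `--seed`
to keep the Monte-Carlo error of each reported value well below its printed
precision.

## Known limitations

* The sequential-SS table refits nested models; for very large designs a
  sweep-based decomposition would be cheaper.
* Back-transformed SEMs use the delta method, which understates asymmetry
  for large log-scale SEMs (irrelevant at the SEMs produced here).
* The homogeneity screen and Tukey HSD assume homoscedastic Gaussian
  residuals; no robust/non-parametric alternatives are provided.
* Mixed models (acclimation tank as a random effect) are out of scope; tank
  identity is carried through the tables so such a robustness fit can be run
  elsewhere.
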