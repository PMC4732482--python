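# acclim

A thermal-acclimation physiology toolkit for cold-water fish studies. It
covers the full analysis chain of a common-garden population × acclimation
temperature experiment — the kind run on juvenile salmonids held at several
temperatures and assayed for metabolic performance and upper thermal
tolerance:

* **Respirometry reduction** — closed-phase dissolved-oxygen traces are fit by
  least squares and converted to whole-animal oxygen consumption with
  `MO2 = (decline rate − blank rate) × (V − Vm) × 60` (mg O₂ h⁻¹; V = chamber
  volume, Vm = fish volume, in litres), with bacterial background respiration
  estimated from blank chamber runs and subtracted on the concentration
  scale. Routine metabolic rate (RMR) is the mean of three closed-phase
  estimates; maximal metabolic rate (MMR) is back-extrapolated from the
  post-exhaustion recovery series by regressing MO₂ on ln(minutes since
  chamber re-entry) and reading the curve at t = 1 min; aerobic scope is
  MMR − RMR, and the log-time slope is the metabolic recovery-rate statistic.
* **Thermal tolerance** — loss-of-equilibrium events on a constant
  0.17 °C min⁻¹ ramp become per-fish critical thermal maxima (CTmax), whether
  recorded as elapsed time or as temperature.
* **Inference** — two-factor ANOVA/ANCOVA with body mass as covariate
  (sequential sums of squares, covariate first), homogeneity-of-regression-
  slopes screening, adjusted least-squares means at a reference mass
  (108.6 g by default) with delta-method SEMs on the back-transformed scale,
  allometric mass exponents as the common log₁₀–log₁₀ ANCOVA slope
  (`rate = a·mass^b`), Tukey HSD pairwise comparisons on the adjusted means,
  and Fulton's condition factor `K = 100·M/L³`.
* **Synthetic data** — a calibrated generator that emulates the full
  4 population × 4 temperature design (158 respirometry fish, 160
  thermal-challenge fish), so every stage is testable end to end without any
  field data: linear O₂ declines with probe noise and bacterial background,
  logarithmic post-exercise recovery sampled as eight 5-min windows
  alternating with 5-min flushes over 75 min, Gaussian loss-of-equilibrium
  temperatures, and log-normal body masses with imposed RMR/MMR allometries.

## Worked example

```python
import acclim as a

cfg = a.default_respirometry_config()
study = a.simulate_respirometry_study(cfg, seed=1)
summary = a.process_study(study["fish"], study["traces"],
                          study["recovery"], study["blanks"])
data = study["fish"].merge(summary, on="fish_id")

fit = a.two_way_ancova(data, "rmr")          # log10(RMR) ~ log10(mass) + pop * temp
print(fit.anova_table.round(4))
b, se = a.mass_exponent(data, "rmr")
print(f"mass exponent: {b:.3f} +/- {se:.3f}")
print(a.adjusted_means(fit, "acclimation_temp", reference_mass=108.6).round(3))
```

prints

```
                                df  sum_sq  mean_sq         F  PR(>F)
log10(mass)                    1.0  0.1625   0.1625  131.3658  0.0000
population                     3.0  0.0122   0.0041    3.2963  0.0224
acclimation_temp               3.0  3.5460   1.1820  955.6951  0.0000
population:acclimation_temp    9.0  0.0154   0.0017    1.3815  0.2019
Residual                     141.0  0.1744   0.0012       NaN     NaN
mass exponent: 1.089 +/- 0.055
  acclimation_temp  ls_mean    sem  back_transformed  reference_mass
0             11.0    8.266  0.113              True           108.6
1             15.0   12.270  0.162              True           108.6
2             19.0   13.182  0.247              True           108.6
3              8.0    5.224  0.068              True           108.6
```

Reading this: acclimation temperature dominates routine metabolism
(F₃,₁₄₁ ≈ 956 on 158 fish after the mass covariate), there is no
population × temperature interaction (p ≈ 0.20), the fitted allometric
exponent 1.089 ± 0.055 recovers the generator's truth of 1.12 within one
standard error, and the mass-adjusted RMR of a 108.6 g fish rises roughly
2.5-fold from 8 °C (5.22 mg O₂ h⁻¹, i.e. ≈48 mg O₂ kg⁻¹ h⁻¹) to 19 °C
(13.18 mg O₂ h⁻¹).

The same workflow is available from the shell:

```sh
acclim simulate --out run/ --seed 1        # synthetic fish/traces/recovery/CTmax CSVs
acclim process  --fish run/fish.csv --traces run/traces.csv \
                --recovery run/recovery.csv --blanks run/blanks.csv \
                --out run/summary.csv
acclim ctm      --events run/ctm_events.csv --out run/ctm.csv
acclim all      --out run/ --seed 1        # full pipeline + report.txt + manifest
```

Every output CSV carries the run seed and a configuration digest in its
header comment; re-running with the same seed reproduces each file byte for
byte.

## Layout

```
src/acclim/
  config.py        generator + run configuration, calibrated defaults
  synth.py         synthetic cohort / trace / recovery / CTmax generators
  respirometry.py  slope fits, MO2 formula, RMR/MMR/scope reduction
  thermal.py       ramp arithmetic and CTmax extraction
  inference.py     ANOVA/ANCOVA, adjusted means, Tukey HSD, mass exponents
  workflow.py      end-to-end pipeline, CSV schemas, manifest
  cli.py           `acclim` command-line interface
docs/methods.md    model, assumptions, calibration and numerical choices
```
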