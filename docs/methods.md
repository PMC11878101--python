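# Methods

This note records the modelling choices behind `biliforecast`: the kinetic
model and its parameterization, what the synthetic cohort does and does not
emulate, the numerical machinery, and the known limitations.

## Structural model

Neonatal bilirubin kinetics are represented by a turnover (indirect
response) ODE over postnatal age t in hours:

    dB/dt = k_in(t) − k_out(t)·B,      B(0) = B0
    k_in(t)  = k_in0·exp(−λ_prod·t)
    k_out(t) = k_out,max·t^γ/(t50^γ + t^γ)

The physiological reading: bilirubin production is highest right after
birth (fetal red-cell turnover, shorter erythrocyte lifespan) and declines
roughly exponentially, while hepatic elimination (UGT1A1 conjugation) is
immature at birth and approaches its mature rate with a sigmoid time
course. Their competition produces the characteristic rise–peak–decline
trajectory peaking a few days after birth. This is the *minimal* structure
with that qualitative behaviour; commercial forecasting algorithms in this
space use proprietary model structures, and no published equation set was
available to copy, so the structural form here is a package design choice
and everything downstream treats it as configuration.

### Default fixed effects

| parameter | value | units | meaning |
|---|---|---|---|
| k_in0     | 3.2    | µmol/L/h | production scale at birth |
| λ_prod    | 0.0035 | 1/h      | production decay rate |
| k_out,max | 0.032  | 1/h      | mature elimination rate constant |
| t50       | 105    | h        | half-maximal elimination maturation |
| γ         | 3.0    | —        | maturation sigmoidicity |
| B0        | 35     | µmol/L   | cord-level concentration at birth |

These are calibration constants chosen once so that the reference term
neonate (38.7 weeks, 3500 g, vaginal delivery, no hemolysis) tracks the
clinically expected course: ≈165 µmol/L at 45 h, ≈207 µmol/L at 69 h, peak
≈215 µmol/L near 85 h, slow decline into the second half of the first
week. They are *not* estimates from any clinical dataset.

### Covariate model

- Gestational age shifts t50 multiplicatively as (GA/38.7 wk)^−2: lower GA
  → slower maturation of elimination → later, higher peak.
- Birth weight scales k_out,max allometrically as (weight/3500 g)^−0.25
  (clearance per volume matures with size).
- Cesarean delivery multiplies k_in0 by 0.95; hemolytic disease multiplies
  k_in0 by 1.30 (increased red-cell breakdown). Both are coarse
  multiplicative stand-ins, not mechanistic estimates.
- Sex is recorded for cohort description but does not enter the model; the
  covariates with established predictive value here are GA, weight and
  delivery mode, and adding factors without a functional form to justify
  them would only blur the random effects.

### Random effects and residual error

Random effects η are bivariate normal on (log k_in0, log t50) with
diagonal Ω = diag(0.04, 0.04) — i.e. ≈20% between-subject CV on production
and on maturation timing. Two random effects keep MAP estimation
well-posed with one to three observations; putting them on production and
maturation lets the data shift both the height and the timing of the peak.

Residual error is additive Gaussian per method: σ_TSB = 13.6 µmol/L and
σ_TcB = 25.5 µmol/L (8% and 15% of a 170 µmol/L reference), reflecting the
5–15% assay variability of serum measurements in clinical practice and the
substantially larger variability of transcutaneous optics. The model
enforces σ_TcB ≥ σ_TSB.

## Individual estimation and forecasting

The empirical-Bayes estimate minimises

    Σ_j (y_j − B(t_j; η))²/σ²_method(j) + ηᵀΩ⁻¹η

by Nelder-Mead from η = 0 (objective tolerance 1e-8, first-found optimum;
the prior mode is kept whenever the search cannot improve on it, so the
returned objective never exceeds the η = 0 value). Ω is inverted with a
1e-10 ridge so a semidefinite Ω degenerates smoothly into pinning η at 0.
With no measurements the population-typical (η = 0) forecast is returned.
Forecast horizons are capped at 60 h past the last measurement for
serum-only input and 48 h otherwise; requests beyond the cap raise an
explicit horizon error rather than extrapolating.

The study-sized scenarios feed the estimator one to three measurements;
the implementation accepts denser input as well, which the test suite uses
for the interpolation (small-noise) limit.

The linear ODE is solved by integrating-factor quadrature: cumulative
trapezoids of k_out and of e^K·k_in on a uniform 0.1 h grid, with linear
interpolation to requested times. On this grid the solution agrees with an
adaptive LSODA integration to ~1e-4 relative, and it is cheap enough
(tens of microseconds) to sit inside the optimisation loop. Requested
times must be sorted and nonnegative; the returned concentrations are
clipped at 0 (the clip is inactive except for roundoff).

### Two-stage population calibration

`fit_population_two_stage` is a deliberately simple calibration stand-in,
not a full NLME estimator (no SAEM/FOCE): stage 1 fits each patient's η by
weighted least squares against a template model's structural constants;
stage 2 re-centres k_in0 and t50 at the geometric mean of the individual
values, sets Ω to the sample covariance of the individual log-deviations,
and sets the residual SDs to pooled per-method RMS residuals. The
structural constants without random effects (λ_prod, k_out,max, γ, B0) and
the covariate coefficients are carried over from the template. Two-stage
estimates of Ω are inflated by per-subject estimation noise; recovery
tests therefore check scale, not equality. It requires ≥20 patients with
≥4 measurements each.

## Synthetic cohort

The generator emulates the statistical structure the validation needs:

- **Covariates.** GA and weight are truncated skew-normals tuned once to
  the quartile targets 37.0/38.7/39.9 weeks and 2670/3155/3510 g (shape
  −8, truncation at the eligibility floors of 34 weeks and 1500 g);
  39% female, 35% cesarean, 8% hemolytic. GA and weight are drawn
  independently — a simplification; real GA–weight correlation is strong,
  but only the marginals matter for the validation conditions here.
- **Trajectories.** Each patient's true course comes from the turnover
  model with η drawn from Ω; the truth is retained for recovery tests and
  never shown to the predictor.
- **Schedules.** 3–6 measurement times; the first at 24–48 h (12–36 h for
  all-TcB patients, who are screened transcutaneously earlier), later ones
  at 12–36 h gaps, truncated at 120 h. Each patient follows one method
  regime: all-TSB (35%), all-TcB (25%), or mixed (40%, per-measurement
  coin flips with a 5% chance of a paired same-time TSB+TcB, which
  exercises the tie rule). All policy parameters are configuration.
- **Measurement error.** value = truth + offset + N(0, σ_method), floored
  at 0, with offset 0 for TSB and +14.3 µmol/L for TcB (the mean TcB−TSB
  difference reported by device-comparison studies; the direction is
  configurable since reported directions vary across devices and skin
  pigmentation).
- **Determinism.** Every patient draws from substreams keyed by
  (seed, patient_id, purpose): cohorts are reproducible, per-patient
  records do not depend on cohort size, and CSV output is byte-identical
  under a seed.

What the generator does **not** emulate: phototherapy and its feedback on
sampling, feeding and dehydration dynamics, G6PD or immunohematological
detail beyond a production multiplier, TcB offset dependence on bilirubin
level and skin pigmentation, GA–weight correlation, or site/device
heterogeneity. Consequently, passing validation here shows the pipeline is
*self-consistent* — the estimator, rule engine and metrics do what they
claim under the assumed data-generating process — not that the default
model is clinically accurate on real neonates.

## Scenario rules

Windows are closed intervals; selection is greedy first-fit (the first
eligible measurement fills each slot) and the target is the last eligible
measurement within the horizon, with TcB preferred at same-time ties. The
single-input scenario's target uses the same 24–96 h window and 8 h gap as
subsequent inputs. Rejections are tagged (`no_first_measurement`,
`first_window`, `window`, `gap`, `no_target`, `horizon`) and counted per
scenario, so the gap between "met input criteria" and "evaluable with a
target" is explicit in the accounting rather than hidden — the
target-availability filter is typically the largest single cause of
attrition.

## Validation metrics

- The "margin of error of the 95% CI" is the Bland-Altman limits of
  agreement, mean(PE) ± 1.96·SD(PE) with sample SD, reported as the larger
  absolute limit. The SD/√n (CI-of-the-mean) variant exists behind a flag
  for sensitivity analyses; it is much narrower and not the default.
- Mis-prediction tails use strict inequalities (PE < −85, PE > +85);
  percentages are rounded half-away-from-zero to one decimal, which
  reproduces tabulations such as 1/109 → 0.9% and 4/76 → 5.3%.
- The "≥95% of aPE within 85" condition is read as ≥; an exact-boundary
  fraction is flagged in the verdict.
- Medians/IQRs use linear-interpolation quantiles.
- Harmonization maps values onto the target measurement's scale by the
  signed 14.3 µmol/L offset; measurements carry their current reporting
  scale, making harmonization idempotent and exactly invertible.
- The increase rate converts µmol/L differences to mg/dl (17.1 µmol/L per
  mg/dl) before dividing by the time interval, matching the mg/dl-per-hour
  convention of risk-assessment guidance.

## Pipeline conditions and problem sizes

The default study replica uses 276 patients. The self-consistency check of
the two-serum-measurement scenario uses 20 replicates of 300 patients;
distributional calibration checks use 10,000 draws; the scenario-rule
oracle sweep uses 500 patients; two-stage recovery uses 200 patients with
6 measurements each. These sizes give stable statistics for each check
while keeping the whole suite quick to run on a single CPU.

## Known limitations

- The structural model and all default parameter values are package
  calibration choices; none are estimates from clinical data, and no claim
  of clinical validity is made.
- Two random effects cannot capture shape changes beyond peak height and
  timing (e.g. biphasic courses under hemolysis plus phototherapy).
- The two-stage calibrator is biased upward in Ω and is intended for
  synthetic-data calibration exercises only.
- The TcB offset is modelled as constant; in reality it varies with
  bilirubin level, device and skin pigmentation.
- Greedy first-fit scenario selection follows the stated input rules
  exactly; it can reject a patient for whom a non-first-fit measurement
  subset would have been evaluable, which mirrors the rules as written
  rather than maximising yield.
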