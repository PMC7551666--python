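# Methods

## Model

Pediatric clearance is extrapolated from the mean adult clearance of the
same protein by weight-based allometry, CL = CL_adult · (W/W_ref)^b with
W_ref = 70 kg (configurable on `AdultReference`). The exponent b is a
step function of age — the age-dependent-exponent (ADE) schedule: 1.2
for preterm and 1.1 for term neonates up to 0.25 years, 1.0 to 2 years,
0.9 to 5 years, and 0.75 above 5 years. The schedule is data
(`ExponentSchedule`), not code: the CLI accepts overrides, and a user
can supply alternative bands. The model assumes clearance scales with
total body weight alone; it carries no maturation function, no
target-mediated disposition, and no covariates beyond age, weight and
gestational maturity — it is a first-in-pediatric-dose projection tool,
not a population-PK model.

Dose projection is the direct identity Dose = CL × target AUC. Units of
clearance are opaque strings carried through verbatim; the package never
converts between mL/h, mL/day, L/h or mL/min, because the scaling
factor (W/70)^b is dimensionless and each drug's prediction stays in its
adult-clearance units. Dimensional consistency of the AUC supplied to
the dose projection is the caller's responsibility.

## Boundary and input conventions

* Age bands are half-open with inclusive upper bounds: (0, 0.25],
  (0.25, 2], (2, 5], (5, 18). Age 2.0 y maps to b = 1.0 and 5.0 y to
  b = 0.9; 0.25 years is treated as identical to 3 months. This makes
  the exponent lookup total over (0, 18) years. The choice of which
  exponent applies exactly at a band edge is a package convention —
  published descriptions of the schedule are ambiguous at the meeting
  points.
* Maturity (preterm = born before 37 completed weeks, by convention) is
  a caller-supplied flag, never computed, and is required for ages at or
  below 0.25 years; `not_applicable` in that range is an error with an
  actionable message.
* Full precision is kept internally everywhere; display rounding is
  half-away-from-zero, one decimal for clearances and whole percent for
  errors, mirroring how published tables print (7.93 → 7.9,
  −8.14 → −8).

## Weight imputation and age labels

Published pediatric PK tables report age groups, not weights, so
predictions from a table row impute a representative weight in two
steps. The age label is parsed into bounds and its arithmetic midpoint
("6–12 y" → 9.0; "12.3 months" → 1.025 y at 12 months/year; "<2" →
midpoint 1.0 with an implicit lower bound of 0; ">12" → midpoint of
(12, 18), the pediatric ceiling). The midpoint is an unbiased
representative absent any distributional information. Median body weight
at that age then comes from a packaged sex-averaged weight-for-age table
(piecewise-linear interpolation between knots, term stratum 3.4 kg at
birth to 70 kg at 18 years, a short preterm stratum of 1.2–3.0 kg over
the first three months) — values chosen as round numbers representative
of standard pediatric growth medians. Interpolation is exact at knots,
monotone between them, and extrapolation beyond the table span raises
rather than guessing. Callers who know the actual weight should supply
it; the median is a stand-in.

Because the study-specific weights behind the bundled dataset's
published predictions are unknown (only the tocilizumab row prints one,
20 kg), model-basis re-predictions of the bundled rows are *not*
expected to reproduce the printed predicted-clearance cells, and the
package does not claim they do. Three canakinumab rows whose age groups
were never published carry explicit overrides instead of guessed ages:
an exponent override (0.9 for the youngest series entry — "youngest may
be 4 years" — and 0.75 for the other two) and a weight override
back-calculated from the published prediction itself (synthetic
stand-ins; those rows are by construction circular under the model basis
and carry no evidential weight there). The printed-basis evaluation,
which is what the headline counts use, never touches imputed weights.

## Evaluation

The accuracy statistic is the signed percent prediction error
(predicted − observed)·100/observed, binned symmetrically on absolute
value at 30% and 50%. Both thresholds are inclusive — a −50% row counts
as acceptable — so the ≤50% and >50% bins partition the observations;
this inclusivity is forced by the partition requirement and by how
boundary rows are counted in the published per-class tallies. Binning
defaults to the unrounded recomputed errors; a `rounded` flag bins on
whole-percent errors instead, mimicking binning on printed integer
columns (which convention the original analysis used is unstated).

Errors recomputed from printed clearance cells differ from the printed
error column by up to a few points because the printed cells are
rounded; fixture validation allows ±5 points before declaring a row
corrupt, and `discrepancy_report` lists rows differing by more than 2.
At the 30% boundary this rounding flips individual rows, so the
recomputed ≤30% counts (58 of 75 overall) sit slightly below the
published 60; the 50%-threshold counts are robust to it and reproduce
exactly (72 within, 3 over; 32/21/19 by class).

## Synthetic cohorts

The simulator generates data with exactly the structure the model
assumes, which is what makes it useful for calibration checks and
useless as evidence about real children. Within each band (the neonatal
band split into preterm and term strata), ages are uniform, weight is
the growth-reference median at the drawn age times a log-normal factor
(CV `weight_cv`, default 0.15 — typical size variability around a
median), true clearance follows the power law with the band's exponent,
and observed clearance multiplies in log-normal residual noise (CV
`residual_cv`, default 0.3 — conventional proportional PK residual
magnitude; log-normal keeps clearances positive). Log-normal factors are
mean-1 (log-mean −σ²/2). All randomness flows from a single integer seed
through `numpy.random.Generator`; replicates use spawned child seeds, so
every experiment is exactly reproducible.

Exponent recovery refits log CL = log a + b·log W by ordinary least
squares within each band (statsmodels OLS; slope = exponent, antilog
intercept = coefficient). The packaged experiment sizes — 200 subjects
per band, residual CV 0.3, 100 replicates, compared against 20 subjects
per band — are desk-scale choices that already pin the per-band mean
fitted exponent within 0.05 of its generating value and show RMSE
shrinking with n, demonstrating that the neonatal/infant exponents
(1.0–1.2) are statistically distinguishable from the fixed 0.75. What
passing these tests shows is internal consistency (simulate → fit →
recover, simulate → predict → evaluate closes exactly in the noise-free
limit); it does not validate the exponent values against real pediatric
data — the bundled 75-observation evaluation is the empirical check.

## Numerical notes and limitations

* The fixed-exponent comparator (W/70)^(0.75 − b_ADE) quantifies how the
  classical exponent over-predicts small children's clearance (≈3.85-fold
  for a 3.5 kg preterm neonate); it exceeds 1 for every weight below
  70 kg whenever b_ADE > 0.75.
* OLS on two points fits exactly with zero residual degrees of freedom;
  the implementation suppresses the resulting division warning and
  reports the closed-form slope. Fewer than two distinct weights is a
  degenerate design and raises.
* Published-table quirks are preserved, not repaired: one drug appears
  under two indications, one immunoglobulin appears as baseline-corrected
  and uncorrected series of the same drug (drug counts use distinct
  names: 13/7/9), a published per-class error-range statement disagrees
  with that table's own signed cells, and Unicode minus signs are
  normalized to ASCII on read.
* Known limitations: no sex- or percentile-resolved growth modeling, no
  gestational-age-resolved preterm weights, no inference on bin
  proportions, and predictions for age groups wider than one exponent
  band inherit whatever single representative age the midpoint rule
  picks.
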