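# Methods

This note records the models implemented in `leafphys`, the defaults and
why they were chosen, what the synthetic-experiment generator does and does
not emulate, and the numerical decisions that matter when reproducing or
extending the analyses.

## Experimental layout

The package targets a 2 × 2 mixed design: leaf treatment (excised the
evening before vs attached) varies **between** plants; time of measurement
(AM vs PM) varies **within** plants. Default biological replicate counts
per treatment are species-specific — tomato 10, barley 8, maize 12 —
reflecting typical campaign sizes for these crops. All generators accept an
`ExperimentDesign` carrying species, replicate count, seed and a map of
additive effect sizes.

## C3 capacity fitting

Assimilation follows the standard biochemical model of C3 photosynthesis:
`AN = min(Ac, Aj) − Rd` with the Rubisco-limited and
RuBP-regeneration-limited rates given in the README. Kinetic constants are
fixed scalars at the 25 °C measurement temperature (Γ* = 42.75 µmol mol⁻¹,
Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹, so
Km ≈ 710.3 µmol mol⁻¹) — the de-facto community defaults; all are
overridable through `KineticConstants`. No temperature response functions
are applied because the design measures at a single block temperature.
Mesophyll conductance is taken as infinite: all capacities are on a ci
basis. Triose-phosphate limitation is not modelled.

The bilinear fit sorts points by ci and, for every split leaving at least
three points per segment, solves two linear least-squares problems: the
lower segment regresses A on (ci − Γ*)/(ci + Km) (slope = Vcmax, negative
intercept = Rd) and the upper segment regresses (A + Rd) through the origin
on (ci − Γ*)/(4ci + 8Γ*) (slope = Jmax). The winning split minimises the
full-curve SSE against `min(Ac, Aj) − Rd`; ties go to the smaller split
index; the transition ci is the midpoint of the straddling pair. Duplicated
400 µmol mol⁻¹ setpoints are retained as distinct observations. Segments
implying non-positive capacities (numerically, ≤ 10⁻⁶) are skipped; if no
split is admissible the fit is returned flagged unsuccessful rather than
raising, so batch pipelines can count failures.

## C4 capacity fitting

Two separate estimators, as is conventional for maize response curves:

* **Vpmax** from the low-ci subset (default cutoff ci ≤ 100 µmol mol⁻¹,
  configurable because the point-selection rule is a genuine free choice)
  by least squares on `Vpmax·ci/(ci + Kp) − Rd` with Kp fixed at
  80 µmol mol⁻¹ — the sparse low-ci design cannot identify Kp jointly.
  With Kp fixed the model is linear in (Vpmax, Rd) and the optimum is
  computed in closed form; this is the exact solution of the least-squares
  problem, not an approximation. Note that when the curve saturates early
  (low Amax relative to Vpmax), points in the 55–100 µmol mol⁻¹ range may
  already lie on the saturated branch and bias Vpmax downward; choose the
  cutoff below the saturation onset in that case (see
  `examples/fit_aci_curve.py`).
* **Amax** as the horizontal asymptote (Asat + offset) of the
  four-parameter non-rectangular hyperbola
  `A(ci) = [φci + Asat − √((φci + Asat)² − 4θφci·Asat)]/(2θ) + offset`,
  fitted by bounded trust-region least squares with multi-start
  initialisation: φ₀ from the slope of the two lowest-ci points,
  Asat₀ = 1.1·max A, θ₀ = 0.7, offset₀ = min(0, min A), plus five jittered
  restarts; SSE tolerance 10⁻⁸, θ constrained to (0.01, 0.999). A θ
  estimate pinned at a bound raises a warning and sets a flag. The
  reported Amax is the asymptote of the fitted function including the
  offset; whether a day-respiration offset should be excluded is not
  settled usage, so the choice is documented here and both Asat and offset
  are returned.

## NPQ kinetics

NPQ per pulse is (Fm − Fm′)/Fm′, never clipped (mild negative values are
informative). Induction is fitted with `a(1 − e^(−bt))` and relaxation
(time re-zeroed at light-off) with `a·e^(−bt) + c`; a and b are bounded
below by zero, the sustained-quenching offset c is free in sign. Fits are
unweighted least squares with parameter-step tolerance 10⁻¹⁰ and three
jittered restarts; initial values come from the trace (final NPQ for
amplitudes, a log-linearisation of the first half for the induction rate).
"Maximum NPQ" is defined as the maximum **observed** induction NPQ, not
the fitted amplitude: it stays meaningful when induction has not plateaued
and is robust to transient overshoots. Traces carry an instrument tag
(leaf-chamber vs imaging system) and are never pooled across instruments.

## Reflectance

Spectra live on the 350–2500 nm grid at 1 nm (2151 points) — the
spectroradiometer's sampling; the grid is configurable. Technical
replicates (three by default) are averaged per leaf before any analysis.
The spectra-wide test runs an independent one-way ANOVA per wavelength per
time-point, with the Bonferroni threshold computed as α divided by the
number of wavelengths *actually tested in that invocation*, never a
hard-coded 2151. Wavelengths with zero total variance report F = 0, p = 1
with a warning; zero within-group variance with real separation reports
p = 0. Because neighbouring wavelengths covary in real spectra, Bonferroni
control is conservative there; on the generator's independent-noise nulls
it is close to nominal. The index registry ships five literature-standard
formulas (Datt, MSI, NDVI, PRI, WI) as defaults; any registry of named
band expressions can be supplied. A zero denominator raises an explicit
undefined-value error rather than propagating infinities.

## Inference

With a two-level within factor, the mixed-design ANOVA decomposes exactly:
the treatment effect is a one-way ANOVA on per-subject means (tested
against plant-to-plant variation); the time and interaction effects come
from regressing per-subject PM−AM differences on effect-coded treatment
(intercept = time, slope = interaction, both against the pooled
difference-score residual). For balanced data this reproduces the textbook
sums-of-squares table; for unbalanced data it yields the marginal
(Type-III-style) tests on unweighted group means — the defensible default
when replicate counts differ by accident rather than design. Subjects
missing a time level are dropped listwise with a warning. Sphericity
corrections are moot with only two within levels. Zero residual variance
raises an explicit degenerate-data error. Treatment comparisons of scalar
traits default to Welch's two-sample t-test (plants are independent); a
paired mode (one-sample t on per-pair differences) is available where
pairing is real. No multiple-testing correction is applied across traits —
only the spectra-wide analysis corrects, matching standard practice for
this design. α = 0.05 throughout unless configured.

## Synthetic-experiment generator

The generator's job is to produce data with the exact forward models and
experimental structure the analysis assumes, so that parameter-recovery,
calibration and power claims are checkable end to end.

* **Gas exchange.** C3 curves use the 11-setpoint sequence
  (400, 300, 200, 100, 50, 400, 400, 700, 1000, 1300, 1800 µmol mol⁻¹);
  maize curves the ascending 400–1250 then descending 400–25 sequences
  (5 + 7 points), concatenated in measurement order. ci is a fixed affine
  drawdown of the setpoint — 0.7·setpoint + 15 for C3,
  0.4·setpoint for C4 — with optional jitter. The small C3 offset keeps
  low-setpoint ci above Γ*, mirroring the real tendency of ci to approach
  the ambient value as assimilation falls toward compensation; the
  mapping is otherwise cosmetic because all fitting operates on ci.
  Assimilation noise is additive Gaussian (default 0.3 µmol m⁻² s⁻¹,
  a typical IRGA stability figure). The C4 forward model is
  `min(PEPc-limited, NRH) − Rd`; the saturating branch's initial slope
  defaults to 3.0 mol mol⁻¹, above Vpmax/Kp, so the low-ci response is
  PEPc-limited as in real C4 leaves.
* **Fluorescence.** True NPQ follows the induction/relaxation models at
  the protocol's pulse times (12 pulses over 10 min light, 8 over 12 min
  dark); Fm′ is back-computed as Fm/(NPQ + 1) and perturbed with
  multiplicative log-normal noise (σ = 0.02 by default) because
  fluorescence is strictly positive. Fm and Fo derive from a configurable
  Fv/Fm (default 0.8, a healthy dark-adapted leaf).
* **Spectra.** A fixed parametric green-leaf template (logistic NIR
  shoulder, green-region bump, Gaussian water-absorption dips near 1450
  and 1940 nm, declining SWIR tail) plus treatment-dependent
  compact-support Gaussian effect bands, a per-leaf random deviation and
  per-technical-replicate noise, clipped to [0, 1]. It is qualitatively
  leaf-like, not a radiative-transfer model, and its noise is independent
  across wavelengths — so calibration results on it do not speak to the
  wavelength covariance of real spectra (where Bonferroni becomes
  conservative).
* **Scalar traits.** value = baseline + treatment δ + time δ +
  interaction δ + Gaussian noise, with replicate IDs shared across AM/PM
  (repeated measures) and a non-repeated mode for end-of-day traits.
  Dispersion defaults are free parameters chosen to be plausible (e.g.
  0.02 MPa for water potential), not calibrated to any particular dataset,
  because field campaigns report means far more often than variances.

Every generator is a pure function of its seed; random streams are keyed
by data type and structural position (treatment index, replicate, time),
so enlarging a design never changes draws already generated. What passing
tests on these data show is that the estimators and tests are correct and
calibrated under their assumed models — not that real leaves satisfy those
models.

## Pipeline

Stage order: simulate/load → capacity fitting (tomato/barley → C3
bilinear; maize → C4 Vpmax + hyperbola) → NPQ fitting → spectra-wide tests
and indices per time-point → inference over every trait table produced
upstream. Failed fits are excluded from inference and counted in the
report. Stages are individually selectable, which is also how lightweight
power studies run (trait simulation + inference only). All CSVs use a
canonical 10-significant-digit float format and the JSON report carries no
wall-clock state, so a (config, seed) pair reproduces its output tree
byte-for-byte. The fluorescence CSV is rectangular: each leaf contributes
one `reference` row holding Fm and Fo alongside its pulse rows.

## Problem sizes used in the shipped checks

The acceptance script and statistical tests use 200 simulated curves per
noise level for C3/C4 recovery, 100 seeds for NPQ recovery, 200 null
spectra sets (2151 wavelengths, 8 leaves per group), 500 null simulations
for repeated-measures type-I error, and 100 pipeline runs for the
power contrast — sizes at which the Monte-Carlo standard errors are
comfortably below the tolerances being checked.

## Known limitations

* No mechanistic stomatal/ABA model, cuvette physics, or circadian model
  beyond the additive AM/PM effect; gs is generated, not derived.
* No full enzyme-limited/transport-limited C4 intersection model, no
  light-response fitting, no TPU limitation, no mesophyll conductance.
* The spectra template is phenomenological; index values computed from it
  are internally consistent but not biophysically calibrated.
* The repeated-measures layer implements the classical two-stratum
  decomposition only; designs with more within levels or missing-data
  structure need a likelihood-based mixed model instead.
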