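# Methods

## The generative and analysis model

The package is organised around a four-construct structural model of
perioperative acute kidney injury in infants.  Cardiopulmonary bypass
(CPB) is exogenous; low cardiac output syndrome (LCOS), AKI and the
post-operative Outcome are endogenous, with standardized paths
CPB→AKI 0.596, CPB→LCOS 0.451, LCOS→AKI 0.347 and AKI→Outcome 0.684.
Each construct is measured by 3–4 indicators through the standardized
loadings of the canonical solution (e.g. CPB→bypass-duration 0.997,
LCOS→age −0.661), and two pairs of indicator residuals are correlated
(bypass duration ↔ creatinine-normalized uNGAL, 0.137; in-hospital
mortality ↔ ΔsCr>50 %, 0.197).

Simulation inverts the measurement model, which is standard practice
for covariance-structure recovery studies: latents are generated
recursively (each latent is its parents' weighted sum plus a normal
residual sized so every latent has unit variance), and each indicator
is `loading × latent + residual` with residual variance `1 − loading²`
(floored at 1e-6 for the near-unit loadings).  The two residual arcs
are interpreted as **residual correlations**, not covariances: with a
0.997 loading, the bypass-duration residual variance is 0.006, so a
residual *covariance* of 0.137 would make the 2×2 residual block
non-positive-definite — the printed two-headed-arrow values are only
coherent on the correlation scale, which is also the scale on which
standardized SEM output prints them.  The standardized solution of the
fitting engine reports residual arcs on that same scale, so generation
and recovery are consistent.

### Mortality

In-hospital mortality is generated by thresholding a continuous
propensity at its 96th population percentile (4 % deaths at n = 200)
and analysed as a numeric 0/1 column, matching how a binary outcome is
carried through a metric factor analysis.  Dichotomization attenuates
every moment involving mortality by the point-biserial factor
`φ(z₀.₉₆)/√(0.04·0.96) ≈ 0.44`; a continuous-mortality mode
(`mortality_mode="propensity"`) is therefore provided, and the
parameter-recovery and respecification studies use it, because they
test whether the machinery recovers the generative coefficients — a
question the irreversible information loss of thresholding would
otherwise dominate (the mortality loading would come back as ≈ 0.29
against a generating 0.652 no matter how good the estimator is).

### Raw time-series layer

`simulate_timeseries` emits serum creatinine (6-hourly, 48 h), urine
output and arterial pressures (hourly, 24 h), lactate (6-hourly) and
uNGAL (0–12 h), plus a static record (surgery variables, drug rates,
fluid totals, pre-operative history flags).  Shapes are invented
(level × unit-mean shape × lognormal noise; a Gaussian-bump creatinine
rise); only the *induced correlation* between each derived metric and
its generating construct is contractual.  Channel levels are driven by
standardized propensities carrying the indicator's loading; threshold
metrics keep their signal because within-patient variability smooths
the threshold nonlinearity (urine output uses a log-linear level in the
propensity for the same reason).  Marginal scales follow the cohort
summary statistics where published (bypass 118.2 ± 63.0 min, urine
output ≈ 4.1 ml·kg⁻¹·h⁻¹, lactate 3.7 ± 1.9 mmol/L, fluid balance
−28.06 ml/kg/24 h, …) and are plausible round numbers where not (the
AUC-type metrics, for which no summary is available).

What this generator does **not** emulate: creatinine kinetics or CPB
hemodilution, informative missingness, measurement rounding, and any
residual structure of the real cohort beyond the two modelled arcs.
Passing tests therefore demonstrate that the pipeline recovers a known
latent structure from realistic-looking inputs — not that the clinical
conclusions would replicate on new patients.

## Derived metrics

All repeated measurements are summarised by trapezoidal AUCs over the
channel's monitoring window, optionally normalized by duration;
samples outside the window are clipped with linear interpolation at
the edges.  Threshold metrics (oliguria below 0.5/1/2 ml·kg⁻¹·h⁻¹,
pressure below the age-group first quintile, creatinine excess above
1.5× baseline) integrate the excursion beyond the threshold with exact
interpolated crossing points, so they account for both magnitude and
duration of the excursion.  Choices worth noting:

* the pressure quintile is pooled over the cohort within three age
  strata (≤ 2 days, 3–28 days, > 28 days; the stated strata leave the
  2–3-day boundary ambiguous and we close it at ≤ 2);
* the ΔsCr metrics are normalized by each patient's actual monitoring
  duration, not a fixed 48 h;
* oliguria thresholds are per hour (ml·kg⁻¹·h⁻¹);
* AKIN staging uses the creatinine and renal-replacement criteria only
  (stage 1 ≥ 150 % or +0.3 mg/dl; stage 2 > 200 %; stage 3 > 300 % or
  dialysis); the urine-output criteria are deliberately not applied
  because oliguria enters the analysis as its own family of metrics;
* the vasoactive-inotropic score is
  `dopamine + dobutamine + 100·epi + 100·norepi + 10·milrinone +
  10000·vasopressin` (µg·kg⁻¹·min⁻¹; vasopressin U·kg⁻¹·min⁻¹);
* creatinine is carried in µmol/L with the mg/dl conversion constant
  (88.4) exposed as a module constant.

## Factor analysis and refinement

Extraction is principal-axis factoring with iterated communalities
(start: squared multiple correlations).  Two numerical safeguards keep
the iteration robust on matrices containing near-collinear variable
families: communalities are capped at 0.999 (Heywood-adjacent
estimates otherwise creep towards 1 indefinitely), and the sequence is
damped plus Aitken-Δ²-accelerated, which leaves the fixed point
unchanged but converges slow geometric modes in a handful of steps.
Default tolerance is 1e-4 on the largest communality change, the
precision class of standard EFA software; tests that compare against
the statsmodels implementation tighten it explicitly.  Varimax is
Kaiser-normalized, with each factor sign-fixed so its largest loading
is positive.

The refinement loop chooses the factor count by the latent-root
criterion (eigenvalues of R above 1), sheds trailing factors carried by
fewer than two significant loadings (the scree-style reduction),
rotates, and then drops the single worst offender per round:

* **low loading** — no rotated loading reaches the significance
  threshold.  The threshold is calibrated to sample size (0.40 at
  n = 200 down to 0.30 for n ≥ 350), which is the calibration the 0.40
  rule itself comes from; a fixed 0.40 at n = 2000 would discard
  variables whose population loading is 0.42.
* **low communality** — below 0.10 by default.  A 0.50 cut-off sounds
  conventional but contradicts the canonical retained solution, in
  which the renal indicators have communalities near 0.2; 0.10 removes
  only variables with essentially no common variance.  The 0.50 value
  remains one parameter away.
* **cross-loading** — significant loadings on two or more factors.

Families of interchangeable metrics (three uNGAL expressions, three
oliguria thresholds, ΔsCr metrics + AKIN stage, systolic/mean
pressure) are reduced to one surrogate **before** the loop, choosing
the member with the highest mean |correlation| with the variables
outside the family.  Loadings cannot perform this ranking: collinear
family members dominate whichever factor they share, so the
highest-loading member is simply the most collinear one (empirically
the middle oliguria threshold), not the best representative of the
underlying process.

Adequacy diagnostics are the Bartlett sphericity test
(`χ² = −(n−1−(2p+5)/6)·ln|R|`, df p(p−1)/2) and the
Kaiser–Meyer–Olkin ratio from the anti-image matrix.  Per-factor
variance proportions divide the sum of squared loadings by the number
of variables in the displayed solution by default; the divisor is
configurable because printed eigenvalue/proportion pairs in the
literature are not always mutually consistent.

### What the factor-recovery tests generate

Structure-recovery tests draw from the *published orthogonal
four-factor pattern* (significant loadings only, independent factors),
not from the full structural model.  Under the structural model the
constructs correlate up to 0.75, and an orthogonal four-factor solution
is then unrecoverable even in population (three eigenvalues above 1;
the weakly-measured AKI construct is absorbed by its stronger
neighbours).  The printed sub-0.4 secondary loadings are also excluded
from the generator: the published uNGAL secondary (0.393) sits so close
to the 0.4 cross-loading rule that including it makes the rule fire on
sampling noise in a third of the seeds.  One structural incompatibility
is accepted rather than patched: the pressure metric is *defined* as
the deficit below the age-group quintile, which removes the
age-collinear share of its hemodynamic signal; since age is itself an
LCOS indicator (−0.773), no generator can deliver the published
pressure loading through that metric, and the closure test treats the
pressure family as optional.

## SEM engine

RAM parameterization, all latent variances fixed to 1 (exogenous
directly, endogenous via free residual variances followed by
re-standardization), correlation-matrix input by default so the whole
solution is standardized.  Optimisation is L-BFGS-B on the analytic
gradient (`dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ]`, assembled for all parameters
from two matrix products), followed by expected-information Newton
polishing down to a scaled gradient norm of ~1e-7; start values are
0.5 for all parameters, tolerance 1e-8 on the objective.  `χ² =
(n−1)·F_min`; standard errors come from the inverse expected
information (Moore–Penrose, because near-unit loadings make the
information nearly singular); Heywood cases are flagged by default
with an optional bound-at-zero mode.  Fit indices:
`RMSEA = √(max(χ²−df,0)/(df(n−1)))`, NFI against the free-variances
independence model, the ML GFI `1 − tr[(Σ̂⁻¹S−I)²]/tr[(Σ̂⁻¹S)²]`, and
`BIC = χ² − df·ln n` (the form that yields the negative values quoted
for well-fitting over-identified models).

Modification indices are score tests: `MI = (n−1)g²/(4·ĩ)` where `g`
is the objective gradient in the fixed parameter and `ĩ` its
information Schur complement over the free parameters (the factor 4 is
because the Hessian of F_ML is twice the expected information — the
property "refit drop ≈ MI" is tested directly).  Respecification
greedily frees the highest-MI candidate and keeps it iff BIC falls,
stopping at the first rejection, with a full decision log.

## Path algebra

A fitted standardized model becomes a trace graph: directed edges
carry standardized coefficients, two-headed arcs carry residual
correlations.  Traces are simple paths using at most one arc.  Strict
Wright rules (backward* [arc] forward*) make the summed trace products
equal the model-implied correlation — verified against
`implied_covariance` on random recursive models.  The default mode
additionally admits one forward→backward turn exactly at a covariance
arc, because that is the convention under which compound coefficients
through residual arcs are quoted in applied SEM work (e.g. the
bypass→duration↔uNGAL←AKI trace); such traces are not correlation
components in the classical sense, and `strict=True` excludes them.
`total_effect` accepts a `through=` restriction for compounds quoted
along one named route (the age→AKI compound via LCOS, or a direct-only
comparison term); shared variance is `100 × total²`, computed from the
unrounded total with the 3-decimal-rounded variant alongside for
comparison with printed tables.

## Bootstrap

Case resampling of patients with a fixed model specification, 200
resamples and 95 % percentile intervals by default.  Percentile (not
BCa) intervals with linear interpolation of order statistics are part
of the definition — at B = 200 the interpolation rule is visible in
the 2.5 %/97.5 % endpoints, and the audit trail retains every
per-resample value so the endpoints are exactly re-derivable.
Non-convergent resamples are redrawn up to five times, then counted;
more than 20 % failures aborts.  Refits are warm-started at the
full-sample solution.

## Problem sizes used in validation

Moment-closure checks run at n = 1e5; parameter recovery at n = 5000
over 20 seeds; factor-structure recovery at n = 2000 over 20 seeds;
the end-to-end time-series closure at n = 2000 over 10 seeds; bootstrap
coverage at n = 200, B = 200 over 50 replications.  These sizes give
each stochastic check a comfortable margin relative to its acceptance
band while the full suite stays in the minutes range.

## Known limitations

* The standardized residual correlation attached to a near-unit
  loading (bypass duration ↔ uNGAL, generating value 0.137 with a
  residual variance of 0.006) is intrinsically ill-conditioned: its ML
  estimate divides by a residual variance whose sampling noise is of
  the same order as its value, so single-cohort estimates of that arc
  scatter widely even at n = 5000, and its observed-scale covariance
  (≈ 0.009) is statistically invisible to modification indices at
  n = 2000.  This is a property of the estimand, not the optimiser.
* Binary mortality attenuates every mortality moment by ≈ 0.44; no
  continuous-SEM estimator can undo this (a probit/ordinal link is out
  of scope, as the original analysis treated mortality numerically).
* Percentile bootstrap intervals for standardized paths undercover
  somewhat at n = 200 (measured ≈ 86 % for a nominal 95 % on the
  CPB→AKI path, with all misses on the high side): the estimand is
  correlation-like, so a cohort that draws a high estimate also draws
  a proportionally narrower resampling distribution centred high.
  BCa or a Fisher-z pivot would repair this, but the plain percentile
  method is the one the analysis convention prescribes, so it is what
  the package implements and reports.
* No means structure, no missing-data estimation, no non-recursive
  models, no oblique rotations.
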