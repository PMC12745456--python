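# Methods

## Structural model

FIX activity after intravenous rIX-FP follows linear two-compartment
kinetics. We evaluate everything through the macro-constant (biexponential)
solution rather than an ODE integrator: the rates λ1 ≥ λ2 are the roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0 with k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp,
and the unit-bolus coefficients A = (λ1−k21)/((λ1−λ2)Vc),
B = (k21−λ2)/((λ1−λ2)Vc) satisfy A + B = 1/Vc. Zero-order infusions,
superposition of dose trains and steady state (each mode scaled by its
accumulation factor 1/(1−e^(−λτ))) are all closed-form consequences. The
closed form is exact for linear kinetics and ~10³× faster than integration,
which is what makes cohort × replicate Monte-Carlo cheap; a numerical ODE
integrator exists only in the test suite as an independent oracle (agreement
≤ 0.1% is asserted on fixed and randomized parameter sets).

Numerical guards: Q = 0 degenerates exactly to one compartment (λ2 = B = 0);
a repeated-root pathology (relative eigenvalue gap < 1e−10, unreachable with
realistic parameters but possible under random draws) collapses to one
compartment with pooled volume Vc + Vp. Times are hours internally; days
appear only at reporting boundaries (1 day = 24 h exactly). Activity is
IU/dL throughout, identical to percent of normal for FIX.

## Observation model

FTOT = FEX + BASE + FPP. The prior-product residual decays as
FPP(t) = BSE·e^(−(CL/Vc)t) using the same CL and Vc as the study drug
(separate parameters are not identifiable from the available washout data)
and is zeroed permanently once it falls below min(BSE, screening, 2 IU/dL).
The zeroing time is computed analytically, so the rule is stateless: the
same time always yields the same value. Regimen simulations report the
exogenous component only; BASE and FPP matter for estimation datasets.

## Parameters

Defaults are the published population estimates (reference: 70 kg,
50 IU/kg):

| parameter | value | units | role |
|---|---|---|---|
| CL | 0.550 | dL/h | clearance; weight exponent 0.528 |
| Vc | 65.7 | dL | central volume; weight exponent 0.771, dose exponent 0.281 |
| Q | 0.208 | dL/h | inter-compartmental clearance (no covariates, no IIV) |
| Vp | 19.5 | dL | peripheral volume; weight exponent 0.771 |
| BASE | 0.992 | IU/dL | endogenous baseline, capped at 2 |
| ω²(CL), ω²(Vc), ω²(BASE) | 0.0386, 0.0562, 0.176 | — | log-normal IIV variances |
| σ_p, σ_a (group 1) | 0.181, 0.683 | —, IU/dL | residual error, early studies |
| σ_p, σ_a (group 2) | 0.371, 1.20 | —, IU/dL | residual error, late studies |

Interpretation notes. The printed unit of Q ("dh/h") is read as dL/h. The
IIV entries are variances (their CV% column matches √ω²), whereas the
proportional residual entries are standard deviations (CV% = SD×100); the
two blocks are labeled differently in the source table and we follow that
labeling. Age and Japanese ethnicity carry no parameter effects — age acts
only through weight, ethnicity only as a cohort label.

## Virtual cohorts

The clinical data are unavailable, so cohorts are synthetic and calibrated:

- Age groups <6 / 6–<12 / 12–<18 / ≥18 years with study proportions
  12/15/5/81; ages uniform within group bounds (1–63 years overall).
- Weights are log-normal per group. The group median is back-solved (1-D
  root finding on the clearance power law) so the median *typical* per-kg
  clearance equals the published post-hoc median for that group; the
  geometric CV is 20%, a package choice (the publication gives only
  study-level weight summaries), truncated to generous per-group plausible
  ranges by rejection.
- BASE is log-normal around its typical value, rejected (not clipped) above
  2 IU/dL to preserve the log-normal shape below the cap.
- IIV is diagonal (no η correlations), matching the source analysis's
  retained structure; Q and Vp carry no IIV.
- One root seed; each patient draws from a spawned substream, so cohorts are
  bit-reproducible and stable under regrouping.

What this emulates and what it does not: the generator reproduces the age
structure, the per-kg clearance gradient, the baseline cap and the IIV/error
magnitudes of the study population, but not the real patients' joint
covariate vectors, their occasion structure, assay drift, or adherence.
Passing simulation checks therefore demonstrates internal consistency of the
method at study-like conditions, not agreement with any particular patient's
data. A known tension worth stating: calibrating adult weights to the
published post-hoc per-kg clearance median (0.00822 dL/h/kg) implies a
median adult weight of ~63.6 kg, somewhat below the study's typical adult
weights (~70 kg). Long-interval troughs are sensitive to this, so calibrated
cohort medians for 100 IU/kg q21d come out ~10% below the published 5.0
IU/dL, while the same analytics at 70 kg give 4.8. We keep the calibration —
it is the only published, quantitative anchor for the weight distribution —
and note the bias rather than re-tuning toward table values.

## Regimen summaries

- "Trough" is the steady-state exogenous activity at exactly t = τ;
  Cmax is the activity at the end of the 10-minute infusion; AUCss = dose/CL.
- Single-dose durations are the last down-crossing time of each threshold,
  found by bracketing + vectorized bisection on the biexponential and
  reported on a half-day grid. We round to the *nearest* half day (the grid
  resolution of the published tables); flooring would bias every duration
  −0.25 day on average and systematically undershoot the printed values.
- Monte-Carlo summaries redraw IIV per patient per replicate (covariates
  fixed), pool patients × replicates, and report the median with a 90%
  prediction interval. Attainment percentages are the pooled fraction of
  patient-replicate troughs above the cutoff: this convention is the one
  consistent with the published medians (a regimen whose published median
  trough is 5.3 IU/dL shows ~53% attainment of the 5 IU/dL target, which
  only holds if percentages and medians are computed over the same pooled
  distribution). Summarizing per-patient medians first would collapse the
  IIV and give materially lower percentages (~39% in that case).
- The ≥12-year column pools the two oldest groups in their 5:81 study
  proportion. Ethnicity comparisons run the same model on two cohorts; any
  difference is composition plus Monte-Carlo noise by construction.

## Estimation

The estimator maximizes the Laplace-approximate marginal likelihood of
log-transformed observations: for each individual, −2 log L_i ≈
g(η̂) − n·log 2π + log det(H/2), where g is −2 log of the joint density and
H its Hessian at the empirical-Bayes mode. The combined residual error maps
to per-observation log-scale variance σ_p² + (σ_a/F)²; below-LLOQ values
enter as recorded, uncensored; F and DV are floored at 10⁻³ IU/dL to keep
logs finite. The inner mode search is a damped Newton iteration with a
trust-region cap of 2 log-units per step, η clipped to ±8, finite-difference
gradient/Hessian evaluated as one vectorized batch (gradient-norm tolerance
10⁻⁶ — tighter is below finite-difference noise at this objective scale);
the final Hessian (eigenvalues clipped at 10⁻¹⁰) is reused for the Laplace
determinant. With all ω² = 0 the objective reduces exactly to the
fixed-effects weighted log-scale deviance, which the tests verify against an
independent closed-form computation. The outer problem is L-BFGS-B on
log-transformed parameters (positivity by construction); covariate exponents
are held fixed — they are part of the structural model being recovered, not
re-estimated at desk scale. Standard errors, when requested, come from the
inverse Hessian of the OFV with a delta-method transform back to the natural
scale. This is a standard approximation to conditional-estimation schemes;
agreement is expected in estimates, not objective-function arithmetic, and
because no fit diagnostics of the original analysis are published, the
estimator is validated purely by simulation-recovery.

Residual-noise scale: the dataset simulator defaults to log-scale noise
(DV = F·e^ε, var ε = σ_p² + (σ_a/F)²), the transform-both-sides form under
which the published model was actually estimated and the form the likelihood
assumes; the arithmetic natural-scale form (pred·(1+ε_p)+ε_a, floored at 0)
is available as an option. At σ_p = 0.371 the two differ enough to matter:
fitting log-scale likelihood to natural-scale noise biases CL upward by
~5–7%, so consistency between generator and likelihood is the defensible
default for recovery experiments.

Recovery performance at the study's error magnitudes (12 samples over 504 h
including a predose point, 50 IU/kg single dose): CL, Vc and BASE recover
within a few percent at n = 50–100; ω² within a factor of ~1.5; Q and Vp are
soft — their likelihood is nearly flat (the source analysis itself reports
27% and 16% RSE), and single-replicate estimates of Q can miss by 20–60%
without any optimizer failure (verified: perturbed and truth starts reach
the same optimum, and the optimum genuinely prefers the displaced Q). A
predose (t = 0) sample matters: without it BASE and CL trade off and CL
recovery degrades to ±13%.

The LRT helper compares ΔOFV against χ² quantiles at p = 0.01 (forward,
6.6349 at df = 1) and p = 0.001 (backward, 10.8276); a negative Δ between
nested models warns and is treated as not significant.

The pcVPC rescales observations and simulated replicates by (bin-median
population prediction / individual population prediction), bins times by
quantiles (empty bins dropped with a warning), and reports observed
5/50/95th percentiles with 90% simulation bands from the same residual model
as the likelihood. On model-generated data the observed median falls inside
the 90% band in ~90% of bins; with ~10 bins a single unlucky realization can
dip to 80%.

## Problem sizes

Defaults used by the acceptance script: cohorts of 2,000 patients per
steady-state/duration target (one IIV draw per patient — medians are the
target, replicates add nothing to a pooled median beyond noise), 1,500
patients × 200 replicates for attainment percentages, a 1,130-patient
mixed-age cohort × 100 replicates for exposure, and a 50-patient fit for
estimator recovery; the whole script is a few minutes on one core. These
sizes put Monte-Carlo noise on medians near ±1%, well inside the comparison
tolerances.

## Known limitations

- Linear kinetics only: no saturable distribution or elimination, no
  absorption or lag models (intravenous product).
- The weight–age relationship inside a cohort group is not modeled (ages and
  weights are drawn independently within the group), so covariate effects of
  age beyond group membership are absent by design.
- Diagonal IIV; no inter-occasion variability; no covariate re-screening of
  BMI, liver enzymes, creatinine clearance or hepatitis status.
- Q and Vp are estimable but weakly identified at desk-scale designs; treat
  single-fit values of Q with the same skepticism the published RSE implies.
- The pooled-then-stratified percentile convention and the per-kg-clearance
  weight calibration are documented choices where the source tables are
  ambiguous; both are stated above with their observed consequences.
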