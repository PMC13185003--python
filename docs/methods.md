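# Methods

This note records the models the package fits, the choices made where
the design was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations. Notation: `Y_i` a binary
birth outcome for woman `i`; `X_ij` her Hb (g/L) at visit `j`; `t_ij`
the gestational age (weeks); `T_ij` the trimester; `n_i` ∈ {2, 3} the
number of measurements.

## Preprocessing

Trimesters are the half-open intervals [0, 13), [13, 29), [29, 41]
weeks. The source convention leaves the endpoints 13 and 29 ambiguous;
half-open intervals make the mapping a function, with the boundary week
assigned to the later trimester. Multiple measurements within one
(woman, trimester) are averaged — both the Hb values and the visit
times, the latter because the distributed-lag and additive models need a
representative time for the collapsed record. Outcome flags are derived
strictly: LBW iff birthweight < 2500 g, PTB iff delivery < 37.0 weeks,
SGA iff weight percentile < 10 (a simplified percentile rule; a growth-
standard percentile computation is out of scope). Missing outcome
components stay missing and drop a woman from that outcome's analyses
only. A plausibility range of 40–200 g/L guards against g/dL inputs.

Four methods (residual, two-stage, distributed-lag, trajectory mixture)
run on the subset with one Hb value per trimester (`n_i = 3`); the
stratified additive model uses all women.

## Synthetic cohort generator

The generator defines the study conditions every test and validation
study runs under:

| parameter | default | why |
|---|---|---|
| n_subjects | 6452 | the design's cohort size |
| prop_three_visits | 676/6452 | the observed 2-vs-3-visit split |
| trimester means | 119.7, −8.7, −6.25 g/L | first-trimester mean and contrasts |
| visit centers | 10, 24, 32 weeks | observed median visit times |
| visit jitter | ±2 weeks, triangular, truncated to the trimester | observed IQRs of ~2–3 weeks |
| sd_random_intercept | 11 g/L | see below |
| sd_random_slope (T2, T3) | 9.5 g/L | see below |
| sd_noise | 8 g/L | see below |
| outcome prevalences | LBW 18.6%, PTB 6.4%, SGA 30.9% | observed marginal rates |

The three variance components are not published for this design; they
were chosen once so that the implied standard errors of the trimester
fixed effects at n = 676 match the printed precision of those contrasts
(CI half-widths ≈ 1.1 g/L both for the intercept and the contrasts),
i.e. `sqrt(σ_b² + σ_e²)/√676 ≈ 0.55` and
`sqrt(σ_s² + 2σ_e²)/√676 ≈ 0.57`. Two-visit women get an enrollment
visit in the first or second trimester plus an end-of-gestation visit.

Outcome links: `null` (constant logit at the configured prevalence),
`random_effect_link` (logit linear in the true subject random effects),
`class_link` (class-specific intercepts). Window and group-shift
fixtures generate smooth weekly latent Hb curves (population U-shape —
quadratic with nadir ≈ 110 g/L near week 24 — plus subject intercept and
a small linear drift) and tie the outcome to mean centered Hb inside a
gestational window, or shift one group's mean before a cutoff week.
Continuous delivery measurements (birthweight, delivery week, weight
percentile) are synthetic stand-ins drawn on the correct side of each
outcome's cutoff; they carry no joint distribution beyond consistency
with the flags.

What the generator does **not** emulate: country-level heterogeneity
across contributing datasets, device or blood-source measurement
differences, altitude/smoking adjustment, covariate structure
(age/parity/BMI), and correlation between the three outcomes beyond
what a shared link induces. Passing tests therefore demonstrate that
the estimators work under the design's statistical structure, not that
any particular substantive finding generalizes to field data.

## Estimation core

- **OLS** via least squares with an explicit rank check.
- **Logistic regression** by IRLS with step-halving. Wald (not profile)
  95% intervals throughout, matching the symmetric OR-scale intervals
  conventional in this literature. Separation is declared when a
  standardized coefficient passes ±15 *and keeps growing* while the
  deviance still improves *and* ≥1% of fitted probabilities have
  collapsed to 0/1; the last condition prevents false alarms in highly
  collinear cross-basis designs, where large offsetting coefficients
  are a legitimate interior MLE.
- **Linear mixed model** by REML, profiling the residual variance and
  parameterizing the scaled random-effect covariance via its Cholesky
  factor. The criterion is evaluated blockwise per subject (batched by
  block size, with a fast path when all subjects share one random
  design), making a 676-woman refit take ~0.3 s — cheap enough for the
  500-replicate calibration studies. Optimization is Nelder-Mead with
  multi-start plus a tight polish pass. BLUPs are the standard
  empirical-Bayes predictors at the estimated components.
  statsmodels' MixedLM serves as an independent cross-check in the test
  suite, never as the implementation.
- **Natural cubic splines** in the truncated-power construction: with
  m interior knots the basis has dimension m+1 (no intercept), is
  linear beyond the boundary knots, and exposes a second-derivative
  penalty matrix computed by fine-grid quadrature (the integrand is
  piecewise linear, so grid error is negligible).
- **Standardization** uses the sample (n−1) SD.

### A non-identifiability in the two-stage design

With trimester indicators as both fixed and random effects and exactly
one measurement per trimester, each woman's random design `Z_i` is a
square invertible 3×3 matrix, so `σ²I = Z_i (σ² (Z_i'Z_i)^{-1}) Z_i'`
can be traded into the random-effect covariance `G` along a flat REML
ridge: the (G, σ²) split is not identified. The fixed effects, their
covariance, and the marginal covariance `Z G Z' + σ²I` *are* identified
(and agree with an independent mixed-model implementation to ~1e-11);
the BLUP values depend on the ridge point the optimizer reaches, which
is deterministic for a given dataset and seed. Null calibration of
Stage 2 is unaffected (under the null, coverage holds whatever
covariates the BLUPs happen to be); users comparing Stage-2
coefficients across software should expect ridge-point differences.

## Method-specific choices

**Residual method.** The two auxiliary regressions are fitted
independently (their coefficient symbols are reused but not shared);
each residual vector is standardized on its own. First-visit Hb enters
unstandardized with its OR reported per 5 g/L for comparability.

**Two-stage.** Unstructured 3×3 random-effect covariance. BLUPs are
divided by 5 before Stage 2 so ORs read per 5 g/L. Stage 2 uses all
three BLUP columns (intercept and both trimester slopes). Treating
BLUPs as observed attenuates Stage-2 slopes toward zero relative to a
regression on the true random effects; the test suite demonstrates this
attenuation against the generator's ground truth rather than hiding it.

**Distributed lag non-linear model.** Weekly profiles on weeks 1–39 by
linear interpolation between visits and constant extrapolation outside
them, with per-week provenance (observed/interpolated/extrapolated)
recorded so sensitivity analyses can down-weight extrapolated weeks.
Gestational week is used directly as the lag index (lag = 39 − week is
the same axis relabeled). The exposure basis is centered at the
110 g/L reference, so the +5 g/L contrast is exact and OR(week) = 1
identically at zero increment. The default AIC grid crosses exposure
∈ {linear, natural spline with 2–3 quantile knots} with lag ∈
{constant, linear, natural spline with 2 equally spaced knots}. Note a
structural limit: three observed visits leave roughly three identifiable
degrees of freedom of lag shape, so richer lag bases are near-collinear
after profile construction; AIC accordingly tends to select the
constant or linear lag, and the window-recovery studies use the
level+tilt resolution.

**Stratified additive mixed model.** Shared-plus-difference
parameterization: `β0 + αY + f_s(t) + Y·f_d(t) + b_0i`, both smooths
sum-to-zero-centered natural splines of capped dimension (default 5;
the cap is the "limited degrees of freedom" guard against overfitting)
with second-derivative penalties, plus an unpenalized group main
effect. Smoothing parameters and the random-intercept variance are
REML-estimated; all penalized blocks are folded into one penalized
least-squares system whose subject block is eliminated by a Schur
complement, so cohorts of several thousand women fit in well under a
second. The REML surface can hold local optima in the smoothing
parameters; four fixed starts (light/heavy/asymmetric smoothing) are
tried and the best kept. "EDF of the group difference" is the trace of
the difference-smooth influence block: 1 when the difference is shrunk
to the penalty null space (a centered line), up to the basis dimension.
Confidence bands are pointwise delta-method bands at the population
level (random intercept at its mean of 0). Predictions outside the
observed gestational-age range are refused. Output is a description of
Hb trajectories by outcome status — the reverse model yields no outcome
effect estimate, and the reporting keeps that framing.

**Trajectory mixture.** Classic fixed-effects mixture — no within-class
random effects, since with ≤3 measurements per woman class-specific
random effects are weakly identified; the posterior machinery is
agnostic to this choice. Shared residual SD across classes. EM with
seeded multi-start (default 20 restarts; quantile-split initialization
on jittered subject means), convergence at relative log-likelihood
change < 1e-8, an empty class triggering a counted restart. The
observed-data log-likelihood trace is stored and asserted monotone.
Degree (linear vs quadratic) is chosen first on the one-class model by
BIC; K = 1..7 then compared by BIC subject to every modal class holding
≥5% of women (AIC is also reported). Labels are canonicalized by fitted
mean Hb at week 24, descending. Outcome regressions use the largest
class as reference, in modal-indicator or posterior-probability form;
the two coincide for hard posteriors.

One behavior worth flagging: when between-subject heterogeneity is
continuous (a random intercept) rather than discrete, BIC will
correctly prefer K ≥ 2 — the mixture approximates the continuous
distribution. A genuine single-class null for this model family has no
between-subject heterogeneity at all, and the selection-consistency
studies are constructed accordingly.

## Validation studies and problem sizes

The real cohort is restricted, so validation is property-based against
the generator's ground truth (module `hbtraj.validation`; the study
sizes below are the package's choices balancing Monte-Carlo error
against runtime):

- *Estimator oracles*: OLS vs a dense normal-equations solve (1e-8);
  the logistic MLE dominates a surrounding coefficient grid; a
  saturated 2×2 fit reproduces the cross-product OR exactly;
  balanced-design REML matches the closed-form ANOVA estimator (1e-6).
- *Recovery*: Stage-1 fixed effects over 60–100 replicate cohorts at
  n = 1000 (mean within 3 Monte-Carlo SEs of 119.7/−8.7/−6.25); a
  20 g/L-separated two-class mixture at 6 g/L noise (Bayes-optimal
  assignment accuracy > 99.5%, so the ≥99% agreement bar tests the
  estimator, not irreducible overlap); K = 3 selection for a separated
  three-class truth.
- *Null calibration*: ≥500 outcome-independent replicates for the
  residual, two-stage and group-membership ORs (coverage 95% ± 2%);
  200 replicates for the weekly distributed-lag bands (≥90% per week).
- *Structure recovery*: a planted weeks-30–39 window effect localized
  by peak |log OR| (15–20 replicates at n = 2000); a pre-week-20 group
  shift of −5 g/L detected early and not late (8–10 replicates at
  n = 5000).

## Numerical conventions

IRLS converges on relative deviance change < 1e-10 (max 100
iterations); REML optimizations use Nelder-Mead (tolerances 1e-4/1e-6,
polished to 1e-9/1e-11); EM tolerance 1e-8 relative; AIC ties break
toward smaller basis dimension then lexical label; posterior ties in
modal assignment go to the lower canonical label and are flagged;
boundary (zero) variance estimates are flagged, not fatal. All
randomness flows from explicit integer seeds through a single
`numpy.random.default_rng` stream per generated cohort; identical seeds
give bit-identical cohorts.

## Limitations

No covariate adjustment anywhere (by design, matching the methodology
being illustrated). Stage-1 uncertainty is not propagated into Stage 2.
The weekly exposure profiles are interpolations of 2–3 points, not
measurements; provenance flags make this explicit but the
distributed-lag estimates inherit the interpolation assumption.
Additive-model bands are pointwise, not simultaneous. The SGA rule is a
percentile stand-in. Extension of the residual method beyond n_i = 3 is
deliberately not offered.
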