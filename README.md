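# hbtraj — repeated maternal hemoglobin and birth outcomes

`hbtraj` implements five complementary statistical strategies for
relating **repeated maternal hemoglobin (Hb) measurements during
pregnancy** to **binary birth outcomes** — low birth weight (LBW,
< 2500 g), preterm birth (PTB, < 37 weeks) and small-for-gestational-age
(SGA, < 10th weight percentile). It is aimed at biostatisticians and
nutrition-epidemiology analysts who have 2–3 Hb values per woman
(g/L, indexed by gestational age in weeks) and want to compare what
different modeling strategies say about the same cohort.

Because real multi-country pregnancy cohorts of this design are
restricted, the package ships a **synthetic cohort generator** that
reproduces the design's statistical structure (visit times centered at
gestational weeks 10/24/32, trimester-level fixed effects, subject
random intercepts and slopes, latent trajectory classes, realistic
outcome prevalences) together with its ground truth, so every method is
exercisable and testable end to end.

## The five methods

With `Y_i` a binary outcome, `X_ij` the Hb value of woman `i` at visit
`j`, `t_ij` the gestational age and `T_ij` the trimester:

1. **Residual logistic regression** (`hbtraj.residuals`). Sequentially
   residualize later visits on earlier ones,
   `X_i2 = a0 + a1 X_i1 + e_i1` and `X_i3 = a0 + a1 X_i1 + a2 X_i2 + e_i2`,
   standardize the residuals, then fit
   `logit P(Y_i=1) = b0 + b1 X_i1 + b2 ê_i1 + b3 ê_i2`.
   ORs for the residual terms are per 1 SD; this isolates
   window-specific Hb *change* while avoiding collinearity.
2. **Two-stage mixed-effects model** (`hbtraj.two_stage`). Stage 1:
   linear mixed model of Hb on trimester indicators (2nd vs 1st, 3rd vs
   1st) as both fixed and random effects; Stage 2: logistic regression
   of each outcome on the subject-level BLUPs, scaled so ORs read per
   5 g/L of individual deviation.
3. **Distributed lag non-linear model** (`hbtraj.dlnm`). Expand each
   woman's sparse visits to a weekly exposure profile on weeks 1–39,
   build an exposure×lag cross-basis, select the basis by AIC, and
   report the per-week OR of a +5 g/L deviation from the 110 g/L
   reference with pointwise 95% bands — the tool for locating critical
   gestational windows.
4. **Stratified additive mixed model** (`hbtraj.gamm`). The reverse
   model `X_ij = β0 + b_0i + f1(t_ij)(1−Y_i) + f2(t_ij)Y_i + ε_ij` with
   penalized natural-spline smooths and a subject random intercept;
   outputs predicted Hb trajectories by outcome status with bands and
   the effective degrees of freedom (EDF) of the group difference.
5. **Group-based trajectory modeling** (`hbtraj.gbtm`). A finite
   mixture of polynomial Hb trajectories fitted by multi-start EM;
   K = 1..7 compared by BIC under a ≥5% membership floor; women assigned
   to their highest-posterior class; outcomes regressed on class
   membership (modal or posterior-weighted).

`hbtraj.estimation` provides the shared machinery (OLS, IRLS logistic
regression with separation detection, a blockwise profiled-REML linear
mixed model with BLUPs, natural cubic spline bases).

## Worked example

```python
from hbtraj import SimConfig, simulate_cohort, preprocess, subset_by_visit_count
from hbtraj.two_stage import run_two_stage

cohort, truth = simulate_cohort(SimConfig(n_subjects=6452, seed=1))
full = preprocess(cohort)              # trimesters, within-trimester averaging
three = subset_by_visit_count(full, 3) # women with one Hb value per trimester

res = run_two_stage(three, outcomes=("lbw",), seed=1)
print(res.stage1.fixed_ci().round(2).to_string(index=False))
print(res.stage2["lbw"].or_table().round(3)[["term", "scale", "or", "or_lo", "or_hi"]]
      .to_string(index=False))
```

Output:

```
      term  estimate     lo     hi
 intercept    120.27 119.26 121.28
trimester2     -9.48 -10.55  -8.41
trimester3     -6.84  -7.94  -5.73
           term      scale    or  or_lo  or_hi
      intercept per 1 unit 0.237  0.196  0.287
 blup_intercept  per 5 g/L 0.995  0.887  1.117
blup_trimester2  per 5 g/L 1.053  0.866  1.281
blup_trimester3  per 5 g/L 0.964  0.823  1.129
```

Stage 1 says mean Hb is about 9.5 g/L lower in the second trimester and
6.8 g/L lower in the third than in the first (this seed's draw around
the generator's 119.7/−8.7/−6.25 truth). Stage 2's ORs per 5 g/L of
subject-level deviation all cover 1 — correct here, since this cohort's
outcomes were simulated independently of Hb.

## Command line and analysis scripts

```bash
hbtraj simulate --config config.yaml --out data/
hbtraj fit      --config config.yaml --data data/ --out results/
hbtraj report   --out results/
```

The numbered scripts under `analysis/` run the full narrative on the
simulated study-scale cohort: `01_simulate_cohort.py` (design summary),
`02_fit_all_methods.py` (all five methods, JSON + figures),
`03_null_calibration.py` (CI coverage under a null),
`04_parameter_recovery.py` (recovery of generator truth),
`05_window_structure.py` (critical-window and early-shift recovery).
Their tables are written under `results/`.

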