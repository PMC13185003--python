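"""Monte-Carlo validation studies.

The study-scale numerical results the five methods produce on the real
cohort are not reproducible without the restricted data, so the package
validates itself by simulation: parameter recovery against the
generator's ground truth, confidence-interval calibration under
outcome-independent nulls, and qualitative recovery of planted
gestational-window structure. These studies are used both by the test
suite and by the standalone acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import preprocess, subset_by_visit_count
from .dlnm import (
    CrossBasisSpec,
    build_exposure_profiles,
    fit_dlnm,
    predict_or_curve,
)
from .estimation import EstimationError
from .gamm import difference_curve, fit_gamm
from .gbtm import assign_groups, fit_gbtm, fit_group_outcome, select_gbtm
from .residuals import compute_residual_features, fit_residual_logistic
from .synthetic import (
    SimConfig,
    simulate_cohort,
    simulate_group_shift_cohort,
    simulate_window_effect_cohort,
)
from .two_stage import STAGE1_NAMES, fit_stage1, fit_stage2

STAGE1_TRUTH = np.array([119.7, -8.7, -6.25])


def _three_visit(cfg: SimConfig):
    cohort, truth = simulate_cohort(cfg)
    return subset_by_visit_count(preprocess(cohort), 3), truth


def stage1_recovery_study(reps=100, n_subjects=1000, seed=0) -> dict:
    """Stage-1 LMM fixed-effect recovery across replicate cohorts."""
    est = np.zeros((reps, 3))
    for r in range(reps):
        three, _ = _three_visit(
            SimConfig(n_subjects=n_subjects, prop_three_visits=1.0,
                      seed=seed + r)
        )
        est[r] = fit_stage1(three, n_starts=1, polish=False).fixed_effects
    mean = est.mean(axis=0)
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(reps)
    return {
        "mean": mean,
        "mc_se": mc_se,
        "truth": STAGE1_TRUTH,
        "z": (mean - STAGE1_TRUTH) / mc_se,
        "within_3se": bool(np.all(np.abs(mean - STAGE1_TRUTH) < 3 * mc_se)),
        "reps": reps,
        "n": n_subjects,
    }


def residual_null_coverage(reps=500, n_subjects=1000, seed=0) -> dict:
    """Coverage of OR=1 by the residual-term CIs under a null outcome."""
    cover = np.zeros(2)
    done = 0
    for r in range(reps):
        cfg = SimConfig(n_subjects=n_subjects, prop_three_visits=1.0,
                        seed=seed + r,
                        prevalences={"lbw": 0.15, "ptb": 0.15, "sga": 0.15})
        three, _ = _three_visit(cfg)
        try:
            fit = fit_residual_logistic(
                compute_residual_features(three), three.outcome_vector("lbw")
            )
        except EstimationError:
            continue
        tab = fit.or_table().set_index("term")
        for j, term in enumerate(("eps1_std", "eps2_std")):
            row = tab.loc[term]
            cover[j] += int(row.or_lo <= 1.0 <= row.or_hi)
        done += 1
    return {"coverage": cover / done, "reps": done, "n": n_subjects,
            "terms": ["eps1_std", "eps2_std"]}


def two_stage_null_coverage(reps=500, n_subjects=400, seed=0) -> dict:
    """Stage-2 CI coverage of OR=1 when outcomes ignore the random effects."""
    cover = np.zeros(3)
    done = 0
    for r in range(reps):
        cfg = SimConfig(n_subjects=n_subjects, prop_three_visits=1.0,
                        seed=seed + r,
                        prevalences={"lbw": 0.2, "ptb": 0.2, "sga": 0.2})
        three, _ = _three_visit(cfg)
        try:
            s1 = fit_stage1(three, n_starts=1, polish=False)
            fit = fit_stage2(s1, three.outcome_vector("lbw"))
        except EstimationError:
            continue
        tab = fit.or_table().set_index("term")
        for j, c in enumerate(STAGE1_NAMES):
            row = tab.loc[f"blup_{c}"]
            cover[j] += int(row.or_lo <= 1.0 <= row.or_hi)
        done += 1
    return {"coverage": cover / done, "reps": done, "n": n_subjects,
            "terms": [f"blup_{c}" for c in STAGE1_NAMES]}


def gbtm_outcome_null_coverage(reps=500, n_subjects=400, seed=0) -> dict:
    """Group-membership OR CI coverage under class-independent outcomes."""
    cover = 0
    done = 0
    for r in range(reps):
        cfg = SimConfig(
            n_subjects=n_subjects, prop_three_visits=1.0, n_classes=2,
            class_proportions=(0.7, 0.3),
            class_polynomials=((120.0, -0.2, 0.0), (100.0, -0.2, 0.0)),
            sd_random_intercept=0.0, sd_random_slope_t2=0.0,
            sd_random_slope_t3=0.0, sd_noise=6.0, seed=seed + r,
            prevalences={"lbw": 0.2, "ptb": 0.2, "sga": 0.2},
        )
        three, _ = _three_visit(cfg)
        try:
            fit = fit_gbtm(three, 2, degree=1, n_restarts=2, seed=r)
            out = fit_group_outcome(fit, three.outcome_vector("lbw"))
        except EstimationError:
            continue
        tab = out.or_table().set_index("term")
        row = tab.loc["class2"]
        cover += int(row.or_lo <= 1.0 <= row.or_hi)
        done += 1
    return {"coverage": cover / done, "reps": done, "n": n_subjects}


def dlnm_null_band_coverage(reps=200, n_subjects=500, seed=0) -> dict:
    """Pointwise coverage of OR=1 per week when no exposure effect exists."""
    cover = np.zeros(39)
    done = 0
    for r in range(reps):
        cfg = SimConfig(n_subjects=n_subjects, prop_three_visits=1.0,
                        seed=seed + r)
        cohort, _, _ = simulate_window_effect_cohort(
            cfg, (1.0, 39.0), effect_per_5g=0.0, outcome="sga",
            base_prevalence=0.2,
        )
        three = subset_by_visit_count(preprocess(cohort), 3)
        try:
            prof = build_exposure_profiles(three)
            fit = fit_dlnm(prof, three.outcome_vector("sga"),
                           CrossBasisSpec("linear", (), "linear", ()))
        except EstimationError:
            continue
        curve = predict_or_curve(fit)
        cover += ((curve.or_lo <= 1.0) & (1.0 <= curve.or_hi)).to_numpy()
        done += 1
    return {"per_week_coverage": cover / done, "reps": done,
            "min_coverage": float((cover / done).min()), "n": n_subjects}


def dlnm_window_localization(reps=20, n_subjects=2000, effect_per_5g=-0.45,
                             window=(30.0, 39.0), seed=0) -> dict:
    """How often the peak |log OR| of the fitted curve lands in the true
    late-gestation effect window."""
    hits = 0
    done = 0
    for r in range(reps):
        cfg = SimConfig(n_subjects=n_subjects, prop_three_visits=1.0,
                        seed=seed + r)
        cohort, _, _ = simulate_window_effect_cohort(
            cfg, window, effect_per_5g=effect_per_5g, outcome="sga",
            base_prevalence=0.2,
        )
        three = subset_by_visit_count(preprocess(cohort), 3)
        try:
            prof = build_exposure_profiles(three)
            fit = fit_dlnm(prof, three.outcome_vector("sga"),
                           CrossBasisSpec("linear", (), "linear", ()))
        except EstimationError:
            continue
        curve = predict_or_curve(fit)
        peak = curve.loc[curve.log_or.abs().idxmax(), "week"]
        hits += int(window[0] <= peak <= window[1])
        done += 1
    return {"hit_rate": hits / done, "reps": done, "n": n_subjects}


def gamm_shift_detection(reps=10, n_subjects=5000, shift=-5.0,
                         before_week=20.0, seed=0) -> dict:
    """Detection of a planted pre-week-20 group shift (and specificity
    after week 20) by the stratified additive mixed model."""
    early = late = 0
    done = 0
    for r in range(reps):
        cfg = SimConfig(n_subjects=n_subjects, seed=seed + r)
        cohort, _ = simulate_group_shift_cohort(
            cfg, shift_g_l=shift, before_week=before_week,
            outcome="ptb", prevalence=0.064,
        )
        try:
            fit = fit_gamm(preprocess(cohort), "ptb")
        except EstimationError:
            continue
        d = difference_curve(fit, np.linspace(8.0, 36.0, 40))
        early += int((d[d.ga_weeks <= 16.0].hi < 0).mean() > 0.5)
        late += int((d[d.ga_weeks >= 26.0].hi < 0).mean() > 0.5)
        done += 1
    return {"early_detection_rate": early / done,
            "late_false_rate": late / done, "reps": done, "n": n_subjects}


def gbtm_two_class_recovery(n_subjects=600, seed=0) -> dict:
    """Recovery of a well-separated (20 g/L) two-class mixture.

    The fixture's 6 g/L noise keeps the Bayes-optimal assignment accuracy
    above 99.5%, so agreement measures the estimator, not class overlap.
    """
    cfg = SimConfig(
        n_subjects=n_subjects, prop_three_visits=1.0, n_classes=2,
        class_proportions=(0.7, 0.3),
        class_polynomials=((120.0, -0.2, 0.0), (100.0, -0.2, 0.0)),
        sd_random_intercept=0.0, sd_random_slope_t2=0.0,
        sd_random_slope_t3=0.0, sd_noise=6.0, seed=seed,
    )
    three, truth = _three_visit(cfg)
    fit = fit_gbtm(three, 2, degree=1, n_restarts=5, seed=seed + 1)
    ass = assign_groups(fit)
    lab = truth.set_index("subject_id").loc[ass.index, "class_label"]
    agreement = float(((ass.modal_class == 1) == (lab == 0)).mean())
    pi_se = np.sqrt(0.7 * 0.3 / fit.n_subjects)
    return {
        "agreement": agreement,
        "pi_hat": float(fit.proportions[0]),
        "pi_within_3se": bool(abs(fit.proportions[0] - 0.7) < 3 * pi_se + 0.02),
        "avg_max_posterior": float(ass.max_posterior.mean()),
        "n": n_subjects,
    }


def gbtm_selection_consistency(reps=6, n_subjects=1000, seed=0) -> dict:
    """How often BIC + the 5% floor select the true K=3 for a
    well-separated three-class truth."""
    hits = 0
    for r in range(reps):
        cfg = SimConfig(
            n_subjects=n_subjects, prop_three_visits=1.0, n_classes=3,
            class_proportions=(0.5, 0.3, 0.2),
            class_polynomials=((130.0, -0.2, 0.0), (112.0, -0.2, 0.0),
                               (94.0, -0.2, 0.0)),
            sd_random_intercept=0.0, sd_random_slope_t2=0.0,
            sd_random_slope_t3=0.0, sd_noise=6.0, seed=seed + r,
        )
        three, _ = _three_visit(cfg)
        best, _ = select_gbtm(three, k_range=range(1, 6), n_restarts=4,
                              seed=seed + 100 + r)
        hits += int(best.n_classes == 3)
    return {"hit_rate": hits / reps, "reps": reps, "n": n_subjects}
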