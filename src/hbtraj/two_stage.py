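"""Method 2: two-stage mixed-effects model.

Stage 1 fits a linear mixed model of Hb on trimester (2nd vs 1st, 3rd vs
1st as both fixed and random effects, unstructured 3x3 random-effect
covariance), yielding per-subject BLUPs of the intercept and the two
trimester slopes. Stage 2 regresses each binary outcome on the three
BLUP columns, scaled so odds ratios read per 5 g/L of subject-level
deviation. The BLUPs are treated as observed in Stage 2, so Stage-2
slopes are attenuated toward zero relative to the link on the true
random effects -- the approach's known limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortData
from .estimation import EstimationError, LMMFit, LogisticFit, fit_lmm, fit_logistic

STAGE1_NAMES = ["intercept", "trimester2", "trimester3"]


@dataclass
class TwoStageResult:
    stage1: LMMFit
    stage2: dict  # outcome -> LogisticFit (or the EstimationError raised)
    blup_scale: float


def fit_stage1(cohort: CohortData, seed=0, **lmm_kwargs) -> LMMFit:
    """Stage-1 LMM: intercept + two trimester indicators, random = same."""
    v = cohort.visits
    if "trimester" not in v.columns:
        raise EstimationError("trimester not assigned; preprocess the cohort first")
    X = np.column_stack(
        [
            np.ones(len(v)),
            (v["trimester"] == 2).to_numpy(float),
            (v["trimester"] == 3).to_numpy(float),
        ]
    )
    y = v["hb_g_l"].to_numpy(float)
    groups = v["subject_id"].to_numpy()
    return fit_lmm(
        X, X, y, groups,
        fixed_names=STAGE1_NAMES, re_names=STAGE1_NAMES, seed=seed,
        **lmm_kwargs,
    )


def fit_stage2(stage1: LMMFit, outcome: pd.Series, blup_scale=5.0) -> LogisticFit:
    """Logistic regression of one outcome on the scaled BLUP columns."""
    blups = stage1.blups / blup_scale
    tab = blups.join(outcome.rename("y"), how="inner").dropna()
    y = tab["y"].to_numpy(float)
    X = np.column_stack([np.ones(len(tab))] + [tab[c] for c in STAGE1_NAMES])
    names = ["intercept"] + [f"blup_{c}" for c in STAGE1_NAMES]
    scales = {f"blup_{c}": (1.0, f"per {blup_scale:g} g/L") for c in STAGE1_NAMES}
    return fit_logistic(X, y, names=names, scales=scales)


def run_two_stage(cohort: CohortData, outcomes=("lbw", "ptb", "sga"),
                  blup_scale=5.0, seed=0, **lmm_kwargs) -> TwoStageResult:
    """Both stages; Stage-1 failure aborts Stage 2 with a composite error."""
    try:
        stage1 = fit_stage1(cohort, seed=seed, **lmm_kwargs)
    except EstimationError as exc:
        raise EstimationError(f"Stage 1 failed, Stage 2 not attempted: {exc}") from exc
    stage2 = {}
    for name in outcomes:
        try:
            stage2[name] = fit_stage2(stage1, cohort.outcome_vector(name), blup_scale)
        except EstimationError as exc:
            stage2[name] = exc
    return TwoStageResult(stage1, stage2, blup_scale)
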