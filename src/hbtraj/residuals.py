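"""Method 1: logistic regression on sequential Hb residuals.

To avoid collinearity among repeated Hb measurements, later visits are
residualized on earlier ones: visit-2 Hb is regressed on visit-1 Hb, and
visit-3 Hb on visits 1 and 2. The standardized residuals capture
window-specific change in Hb beyond what earlier values predict; they
enter an outcome logistic regression together with first-visit Hb:

    logit P(Y=1) = beta0 + beta1*X1 + beta2*eps1_std + beta3*eps2_std

Odds ratios for the residual terms are per 1 SD of the residual; the
first-visit term is reported per 5 g/L for comparability with the other
methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortData, trimester_wide
from .estimation import (
    EstimationError,
    LogisticFit,
    fit_logistic,
    fit_ols,
    standardize,
)


@dataclass
class ResidualFeatures:
    """Per-subject features for the residual method.

    ``table`` has columns x1 (first-visit Hb, g/L), eps1_std, eps2_std
    (standardized residuals), indexed by subject_id; raw residuals are
    kept for orthogonality checks.
    """

    table: pd.DataFrame
    eps1_raw: np.ndarray
    eps2_raw: np.ndarray
    eps1_sd: float
    eps2_sd: float


def compute_residual_features(cohort: CohortData) -> ResidualFeatures:
    """Two sequential OLS fits across subjects; residuals standardized.

    Requires every subject to have exactly one Hb value per trimester
    (visit 1 = trimester 1, etc., after within-trimester collapsing).
    """
    wide = trimester_wide(cohort)
    x1 = wide["x1"].to_numpy()
    x2 = wide["x2"].to_numpy()
    x3 = wide["x3"].to_numpy()
    n = len(wide)
    ones = np.ones(n)

    fit1 = fit_ols(np.column_stack([ones, x1]), x2, names=["a0", "a1"])
    fit2 = fit_ols(np.column_stack([ones, x1, x2]), x3, names=["a0", "a1", "a2"])

    try:
        eps1_std, _, sd1 = standardize(fit1.residuals)
        eps2_std, _, sd2 = standardize(fit2.residuals)
    except EstimationError as exc:
        raise EstimationError(
            f"degenerate fit: residuals are constant ({exc}); later visits "
            "are an exact linear function of earlier ones"
        ) from exc

    table = pd.DataFrame(
        {"x1": x1, "eps1_std": eps1_std, "eps2_std": eps2_std},
        index=wide.index,
    )
    return ResidualFeatures(table, fit1.residuals, fit2.residuals, sd1, sd2)


def fit_residual_logistic(
    features: ResidualFeatures, outcome: pd.Series, x1_scale=5.0
) -> LogisticFit:
    """Outcome logistic regression on (X1, eps1_std, eps2_std).

    ``outcome`` is a binary Series indexed by subject_id; subjects missing
    the outcome are dropped. ORs: residual terms per 1 SD, first-visit Hb
    per ``x1_scale`` g/L.
    """
    tab = features.table.join(outcome.rename("y"), how="inner").dropna()
    y = tab["y"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(tab)), tab["x1"], tab["eps1_std"], tab["eps2_std"]]
    )
    scales = {
        "x1": (x1_scale, f"per {x1_scale:g} g/L"),
        "eps1_std": (1.0, "per 1 SD"),
        "eps2_std": (1.0, "per 1 SD"),
    }
    return fit_logistic(
        X, y, names=["intercept", "x1", "eps1_std", "eps2_std"], scales=scales
    )


def run_residual_method(cohort: CohortData, outcomes=("lbw", "ptb", "sga")):
    """Full method 1: features once, one logistic fit per outcome.

    Returns (features, dict of outcome -> LogisticFit); a per-outcome
    failure (e.g. separation with a rare outcome) is recorded as the
    exception instead of a fit.
    """
    features = compute_residual_features(cohort)
    fits = {}
    for name in outcomes:
        try:
            fits[name] = fit_residual_logistic(features, cohort.outcome_vector(name))
        except EstimationError as exc:
            fits[name] = exc
    return features, fits
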