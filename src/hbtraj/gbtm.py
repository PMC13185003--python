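"""Method 5: group-based trajectory modeling (GBTM).

A finite mixture of polynomial mean trajectories of Hb over gestational
age: subject i belongs to latent class k with probability pi_k, and
within class k her measurements are independent Gaussians around the
class polynomial. Fitted by EM with seeded multi-start initialization;
the number of classes is chosen over K = 1..7 by BIC subject to every
modal class holding at least 5% of subjects; women are then assigned to
their highest-posterior class and outcomes are regressed on class
membership (modal indicators or posterior-probability columns).

Classic fixed-effects GBTM: no within-class random effects (with at
most 3 measurements per woman those are weakly identified); the residual
SD is shared across classes. Class labels are canonicalized by fitted
mean Hb at week 24, descending, so labeling is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_model import CohortData
from .estimation import EstimationError, LogisticFit, fit_logistic

logger = logging.getLogger(__name__)

CANONICAL_WEEK = 24.0


@dataclass
class GBTMFit:
    n_classes: int
    degree: int
    coefficients: np.ndarray  # (K, degree+1), ascending powers of ga_weeks
    sigma: float
    proportions: np.ndarray  # (K,)
    posteriors: pd.DataFrame  # subjects x classes
    loglik: float
    bic: float
    aic: float
    n_subjects: int
    n_params: int
    em_iterations: int
    n_restarts_failed: int = 0
    tie_subjects: list = field(default_factory=list)
    loglik_trace: list = field(default_factory=list)  # winning restart's EM path

    def class_mean(self, t, k):
        return np.polyval(self.coefficients[k][::-1], t)


def _subject_blocks(cohort: CohortData):
    v = cohort.visits.sort_values(["subject_id", "ga_weeks"], kind="stable")
    ids = v["subject_id"].to_numpy()
    uniq, idx = np.unique(ids, return_inverse=True)
    t = v["ga_weeks"].to_numpy(float)
    x = v["hb_g_l"].to_numpy(float)
    return uniq, idx, t, x


def _poly_design(t, degree):
    return np.vander(t, degree + 1, increasing=True)


def _m_step(T, x, idx, m, resp, degree):
    """Weighted per-class polynomial regressions and shared residual SD."""
    K = resp.shape[1]
    coefs = np.zeros((K, degree + 1))
    wrss = 0.0
    wtot = 0.0
    for k in range(K):
        w_obs = resp[idx, k]
        sw = np.sqrt(w_obs)
        A = T * sw[:, None]
        b = x * sw
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        coefs[k] = beta
        r = x - T @ beta
        wrss += float(w_obs @ r**2)
        wtot += float(w_obs.sum())
    sigma = np.sqrt(max(wrss / wtot, 1e-12))
    pi = resp.mean(axis=0)
    return coefs, sigma, pi


def _e_step(T, x, idx, m, coefs, sigma, pi):
    """Posterior responsibilities and observed-data log-likelihood."""
    K = len(pi)
    log_norm = -0.5 * np.log(2.0 * np.pi * sigma**2)
    logf = np.zeros((m, K))
    for k in range(K):
        r = x - T @ coefs[k]
        ll_obs = log_norm - 0.5 * (r / sigma) ** 2
        logf[:, k] = np.bincount(idx, weights=ll_obs, minlength=m)
    logw = logf + np.log(np.maximum(pi, 1e-300))
    norm = logsumexp(logw, axis=1)
    resp = np.exp(logw - norm[:, None])
    return resp, float(norm.sum())


def fit_gbtm(cohort: CohortData, n_classes: int, degree: int = 2,
             n_restarts: int = 20, seed: int = 0, max_iter: int = 500,
             tol: float = 1e-8) -> GBTMFit:
    """EM fit of a K-class polynomial trajectory mixture.

    Multi-start: responsibilities are initialized from a seeded k-means
    style split of subject mean Hb (with jitter per restart); the best
    observed-data log-likelihood across restarts is kept. An empty class
    during EM triggers a restart (counted in the diagnostics).
    """
    if n_classes < 1:
        raise EstimationError("n_classes must be >= 1")
    if degree not in (1, 2):
        raise EstimationError("degree must be 1 (linear) or 2 (quadratic)")
    uniq, idx, t, x = _subject_blocks(cohort)
    m = len(uniq)
    if m < 10 * n_classes:
        raise EstimationError(
            f"{m} subjects is too few for {n_classes} classes (need >= {10 * n_classes})"
        )
    T = _poly_design(t, degree)
    K = n_classes
    rng = np.random.default_rng(seed)
    subj_mean = np.bincount(idx, weights=x, minlength=m) / np.bincount(idx, minlength=m)

    best = None
    failed = 0
    for restart in range(max(n_restarts, 1)):
        # quantile-split init on jittered subject means
        jit = subj_mean + (rng.standard_normal(m) * subj_mean.std() * 0.3
                           if restart > 0 else 0.0)
        edges = np.quantile(jit, np.linspace(0, 1, K + 1))
        labels = np.clip(np.searchsorted(edges[1:-1], jit, side="right"), 0, K - 1)
        resp = np.full((m, K), 0.05 / max(K - 1, 1))
        resp[np.arange(m), labels] = 0.95
        resp /= resp.sum(axis=1, keepdims=True)

        ll_prev = -np.inf
        ok = True
        trace = []
        for it in range(1, max_iter + 1):
            coefs, sigma, pi = _m_step(T, x, idx, m, resp, degree)
            if np.any(pi < 1.0 / (10.0 * m)):
                ok = False
                break
            resp, ll = _e_step(T, x, idx, m, coefs, sigma, pi)
            trace.append(ll)
            if ll < ll_prev - 1e-6:
                raise EstimationError(
                    f"EM log-likelihood decreased ({ll_prev:.6f} -> {ll:.6f})"
                )
            if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
                break
            ll_prev = ll
        if not ok:
            failed += 1
            continue
        if best is None or ll > best[0]:
            best = (ll, coefs, sigma, pi, resp, it, trace)
        if K == 1:
            break  # deterministic, no need for more restarts
    if best is None:
        raise EstimationError(
            f"all {n_restarts} EM restarts failed (empty class) for K={K}"
        )

    ll, coefs, sigma, pi, resp, it, trace = best
    # canonical order: fitted mean at week 24, descending
    order = np.argsort(-np.polyval(coefs[:, ::-1].T, CANONICAL_WEEK))
    coefs, pi, resp = coefs[order], pi[order], resp[:, order]

    n_params = K * (degree + 1) + (K - 1) + 1
    bic = -2.0 * ll + n_params * np.log(m)
    aic = -2.0 * ll + 2.0 * n_params
    posteriors = pd.DataFrame(
        resp, index=pd.Index(uniq, name="subject_id"),
        columns=[f"class{k + 1}" for k in range(K)],
    )
    return GBTMFit(
        K, degree, coefs, float(sigma), pi, posteriors, float(ll),
        float(bic), float(aic), m, n_params, it, failed, loglik_trace=trace,
    )


def assign_groups(fit: GBTMFit) -> pd.DataFrame:
    """Modal class per subject (argmax posterior; ties to the lower label).

    Returns a DataFrame with columns ``modal_class`` (1-based canonical
    label), ``max_posterior`` and ``tie`` flag; the average maximum
    posterior is a standard classification-quality diagnostic.
    """
    P = fit.posteriors.to_numpy()
    modal = P.argmax(axis=1)  # argmax takes the first (lower) label on ties
    mx = P[np.arange(len(P)), modal]
    tie = (np.abs(P - mx[:, None]) < 1e-12).sum(axis=1) > 1
    out = pd.DataFrame(
        {"modal_class": modal + 1, "max_posterior": mx, "tie": tie},
        index=fit.posteriors.index,
    )
    if tie.any():
        logger.info("assign_groups: %d subjects had tied posteriors", int(tie.sum()))
    return out


def select_gbtm(cohort: CohortData, k_range=range(1, 8), degrees=(1, 2),
                n_restarts: int = 20, seed: int = 0, min_share: float = 0.05):
    """Degree then K selection with the >=5% modal-membership floor.

    The polynomial degree is chosen on the one-class model by BIC
    (linear vs quadratic); K is then the smallest-BIC model among those
    whose every modal class holds at least ``min_share`` of subjects.
    If no multi-class model satisfies the floor, falls back to K=1 with
    a warning.

    Returns (best GBTMFit, selection table).
    """
    deg_fits = {d: fit_gbtm(cohort, 1, degree=d, n_restarts=1, seed=seed)
                for d in degrees}
    degree = min(deg_fits, key=lambda d: deg_fits[d].bic)

    rows, fits = [], {}
    for K in k_range:
        try:
            fit = fit_gbtm(cohort, K, degree=degree, n_restarts=n_restarts,
                           seed=seed + K)
            shares = np.bincount(
                assign_groups(fit)["modal_class"].to_numpy() - 1, minlength=K
            ) / fit.n_subjects
            rows.append(
                {"K": K, "degree": degree, "loglik": fit.loglik, "bic": fit.bic,
                 "aic": fit.aic, "min_share": float(shares.min()),
                 "meets_floor": bool(shares.min() >= min_share), "status": "ok"}
            )
            fits[K] = fit
        except EstimationError as exc:
            rows.append(
                {"K": K, "degree": degree, "loglik": np.nan, "bic": np.nan,
                 "aic": np.nan, "min_share": np.nan, "meets_floor": False,
                 "status": f"failed: {exc}"}
            )
    table = pd.DataFrame(rows)
    eligible = table[(table["status"] == "ok") & table["meets_floor"]]
    if eligible.empty:
        warnings.warn(
            "no trajectory model satisfies the 5% membership floor; "
            "falling back to the one-class model", stacklevel=2
        )
        best_k = 1
        if 1 not in fits:
            fits[1] = fit_gbtm(cohort, 1, degree=degree, n_restarts=1, seed=seed)
    else:
        best_k = int(eligible.sort_values(["bic", "K"]).iloc[0]["K"])
    return fits[best_k], table


def fit_group_outcome(fit: GBTMFit, outcome: pd.Series,
                      mode: str = "modal") -> LogisticFit:
    """Logistic regression of an outcome on trajectory-group membership.

    ``mode="modal"``: indicators for each class with the largest class as
    the reference. ``mode="posterior"``: the K-1 posterior-probability
    columns (dropping the largest class) as continuous predictors; with
    hard 0/1 posteriors the two modes coincide.
    """
    if fit.n_classes < 2:
        raise EstimationError("outcome regression needs >= 2 trajectory classes")
    if mode not in ("modal", "posterior"):
        raise EstimationError(f"unknown mode {mode!r}")
    ref = int(np.argmax(fit.proportions))  # largest class = reference
    keep = [k for k in range(fit.n_classes) if k != ref]
    if mode == "modal":
        modal = assign_groups(fit)["modal_class"] - 1
        cols = {f"class{k + 1}": (modal == k).astype(float) for k in keep}
    else:
        cols = {f"class{k + 1}": fit.posteriors.iloc[:, k] for k in keep}
    design = pd.DataFrame(cols, index=fit.posteriors.index)
    tab = design.join(outcome.rename("y"), how="inner").dropna()
    y = tab["y"].to_numpy(float)
    X = np.column_stack([np.ones(len(tab)), tab.drop(columns="y").to_numpy(float)])
    names = ["intercept"] + list(design.columns)
    scales = {c: (1.0, f"vs class{ref + 1}") for c in design.columns}
    return fit_logistic(X, y, names=names, scales=scales)


def run_gbtm(cohort: CohortData, outcomes=("lbw", "ptb", "sga"),
             seed: int = 0, n_restarts: int = 20):
    """Full method 5: selection, assignment, per-outcome group regression."""
    best, table = select_gbtm(cohort, n_restarts=n_restarts, seed=seed)
    assignments = assign_groups(best)
    fits = {}
    for name in outcomes:
        if best.n_classes < 2:
            fits[name] = EstimationError("single trajectory class selected")
            continue
        try:
            fits[name] = fit_group_outcome(best, cohort.outcome_vector(name))
        except EstimationError as exc:
            fits[name] = exc
    return {"fit": best, "selection_table": table,
            "assignments": assignments, "outcome_fits": fits}
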