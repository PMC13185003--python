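"""Method 4: generalized additive mixed model (reverse model).

Hb is modeled as a smooth function of gestational age whose shape may
differ by outcome status, with a subject random intercept:

    X_ij = beta0 + alpha*Y_i + f_s(t_ij) + Y_i * f_d(t_ij) + b_0i + eps_ij

f_s is the shared smooth and f_d the outcome-group difference smooth
(shared-plus-difference parameterization, which makes "the EDF of the
difference between groups" a well-defined trace). Both smooths use a
natural cubic basis with a capped dimension (default 5) and a
second-derivative penalty; the basis columns are centered (sum-to-zero
over the data) so beta0 and alpha carry the levels. Smoothing parameters
and the random-intercept variance are chosen by REML; the subject block
is handled by a Schur complement so cohorts of several thousand women
fit in well under a second.

Group-0 trajectory: beta0 + f_s(t); group-1: beta0 + alpha + f_s(t) + f_d(t).
This is a description of Hb trajectories by outcome status, not an
outcome effect estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import CohortData
from .estimation import ConvergenceError, EstimationError, SplineBasis, Z975


@dataclass
class GAMMFit:
    basis: SplineBasis
    col_means: np.ndarray  # centering constants of the smooth basis
    theta_top: np.ndarray  # [beta0, alpha, f_s coefs, f_d coefs]
    cov_top: np.ndarray  # posterior covariance of theta_top
    sigma2: float
    sigma2_b: float  # random-intercept variance
    lambdas: dict  # smoothing parameters {"shared", "diff", "subject"}
    edf_shared: float
    edf_diff: float
    reml: float
    t_range: tuple
    basis_dim: int
    n_obs: int
    n_subjects: int
    converged: bool

    def _design_row(self, t, group):
        Bt = self.basis.evaluate(np.atleast_1d(t)) - self.col_means
        g = float(group)
        n = Bt.shape[0]
        return np.column_stack(
            [np.ones(n), np.full(n, g), Bt, g * Bt]
        )


def fit_gamm(cohort: CohortData, outcome: str, basis_dim: int = 5,
             maxiter: int = 400) -> GAMMFit:
    """Fit the outcome-stratified additive mixed model by REML.

    Uses all subjects with a non-missing value of ``outcome`` (any number
    of visits). Requires both outcome groups non-empty with >=3 distinct
    gestational ages each.
    """
    y_subj = cohort.outcome_vector(outcome)
    v = cohort.visits.merge(
        y_subj.rename("y"), left_on="subject_id", right_index=True, how="inner"
    )
    if v.empty:
        raise EstimationError(f"no subjects with outcome {outcome!r}")
    t = v["ga_weeks"].to_numpy(float)
    x = v["hb_g_l"].to_numpy(float)
    g = v["y"].to_numpy(float)
    for grp in (0, 1):
        tg = np.unique(np.round(t[g == grp], 6))
        if tg.size < 3:
            raise EstimationError(
                f"outcome group {grp} has {tg.size} distinct gestational ages; "
                "need >= 3 (or the group is empty)"
            )

    t_lo, t_hi = float(t.min()), float(t.max())
    if basis_dim < 3:
        raise EstimationError("basis_dim must be >= 3")
    interior = np.quantile(t, np.linspace(0, 1, basis_dim + 1)[1:-1])
    interior = np.unique(np.round(interior, 6))
    basis = SplineBasis(interior, (t_lo, t_hi))
    K = basis.dim

    B_raw = basis.evaluate(t)
    col_means = B_raw.mean(axis=0)
    Bc = B_raw - col_means
    S = basis.penalty()
    # pseudo-determinant pieces of the penalty (rank K-1: linear null space)
    evals = np.linalg.eigvalsh(S)
    pos = evals[evals > evals.max() * 1e-10]
    rank_S = len(pos)
    logpdet_S = float(np.log(pos).sum())

    top = np.column_stack([np.ones(len(t)), g, Bc, g[:, None] * Bc])
    p_t = top.shape[1]
    sl_s = slice(2, 2 + K)
    sl_d = slice(2 + K, 2 + 2 * K)

    subj_codes, subj_idx = np.unique(v["subject_id"].to_numpy(), return_inverse=True)
    m = len(subj_codes)
    n = len(t)
    counts = np.bincount(subj_idx, minlength=m).astype(float)

    # precomputed cross-products (lambda-independent)
    C = top.T @ top
    M = np.zeros((m, p_t))
    for j in range(p_t):
        M[:, j] = np.bincount(subj_idx, weights=top[:, j], minlength=m)
    r_t = top.T @ x
    r_b = np.bincount(subj_idx, weights=x, minlength=m)
    yy = float(x @ x)

    d_unpen = 2 + 2  # beta0, alpha + one penalty-null direction per smooth

    def pieces(log_lams):
        lam_s, lam_d, lam_b = np.exp(np.clip(log_lams, -20.0, 20.0))
        P_top = np.zeros((p_t, p_t))
        P_top[sl_s, sl_s] = lam_s * S
        P_top[sl_d, sl_d] = lam_d * S
        w = 1.0 / (counts + lam_b)
        S_mat = C + P_top - (M * w[:, None]).T @ M
        try:
            cf = np.linalg.cholesky(S_mat)
        except np.linalg.LinAlgError:
            return None
        rhs = r_t - M.T @ (w * r_b)
        th_top = np.linalg.solve(S_mat, rhs)
        th_b = w * (r_b - M @ th_top)
        # D* = ||y - B theta||^2 + theta' P theta
        quad = (
            th_top @ C @ th_top
            + 2.0 * th_top @ (M.T @ th_b)
            + float(counts @ th_b**2)
        )
        rss_pen = (
            yy - 2.0 * (th_top @ r_t + th_b @ r_b) + quad
            + th_top @ P_top @ th_top + lam_b * float(th_b @ th_b)
        )
        logdet_A = 2.0 * np.log(np.diag(cf)).sum() + float(np.log(counts + lam_b).sum())
        logpdet_P = (
            rank_S * (np.log(lam_s) + np.log(lam_d))
            + 2.0 * logpdet_S
            + m * np.log(lam_b)
        )
        return (lam_s, lam_d, lam_b, S_mat, th_top, th_b, rss_pen,
                logdet_A, logpdet_P)

    def neg2_reml(log_lams):
        pc = pieces(log_lams)
        if pc is None or pc[6] <= 0:
            return 1e12
        rss_pen, logdet_A, logpdet_P = pc[6], pc[7], pc[8]
        sigma2 = rss_pen / (n - d_unpen)
        return (
            (n - d_unpen) * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + logdet_A - logpdet_P
        )

    # REML surface can hold local optima in the smoothing parameters;
    # start from light, heavy and asymmetric smoothing and keep the best
    starts = [np.array([0.0, 0.0, 0.0]), np.array([6.0, 6.0, 0.0]),
              np.array([-4.0, -4.0, 0.0]), np.array([2.0, 10.0, 0.0])]
    res = None
    for x0 in starts:
        cand = optimize.minimize(
            neg2_reml, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise ConvergenceError("GAMM smoothing-parameter optimization failed",
                               trace=[res.message])

    pc = pieces(res.x)
    lam_s, lam_d, lam_b, S_mat, th_top, th_b, rss_pen, _, _ = pc
    sigma2 = rss_pen / (n - d_unpen)
    H_top = np.linalg.inv(S_mat)
    # EDF of a penalized block: K - lam * tr(H_block S)
    edf_s = K - lam_s * float(np.trace(H_top[sl_s, sl_s] @ S))
    edf_d = K - lam_d * float(np.trace(H_top[sl_d, sl_d] @ S))

    return GAMMFit(
        basis=basis, col_means=col_means, theta_top=th_top,
        cov_top=sigma2 * H_top, sigma2=float(sigma2),
        sigma2_b=float(sigma2 / lam_b),
        lambdas={"shared": lam_s, "diff": lam_d, "subject": lam_b},
        edf_shared=float(edf_s), edf_diff=float(edf_d),
        reml=float(-0.5 * res.fun), t_range=(t_lo, t_hi),
        basis_dim=K, n_obs=n, n_subjects=m, converged=bool(res.success),
    )


def predict_trajectories(fit: GAMMFit, ga_grid, group) -> pd.DataFrame:
    """Population-level predicted Hb with pointwise 95% bands.

    The random intercept is set to its mean (0). Grid points outside the
    observed gestational-age range are refused.
    """
    grid = np.atleast_1d(np.asarray(ga_grid, float))
    lo, hi = fit.t_range
    if np.any(grid < lo - 1e-9) or np.any(grid > hi + 1e-9):
        raise EstimationError(
            f"prediction grid extends beyond the observed range [{lo:.1f}, {hi:.1f}]"
        )
    if group not in (0, 1):
        raise EstimationError("group must be 0 or 1")
    Cmat = fit._design_row(grid, group)
    pred = Cmat @ fit.theta_top
    var = np.einsum("ij,jk,ik->i", Cmat, fit.cov_top, Cmat)
    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {"ga_weeks": grid, "group": int(group), "hb_pred": pred,
         "lo": pred - Z975 * se, "hi": pred + Z975 * se}
    )


def edf_of_difference(fit: GAMMFit) -> float:
    """EDF of the group-difference smooth f_d.

    The primary fit is already parameterized as shared + difference, so
    this is the trace of the difference-smooth influence block computed
    at fit time. Ranges from 1 (difference shrunk to a line through the
    centered basis's penalty null space) up to the basis dimension.
    """
    return fit.edf_diff


def difference_curve(fit: GAMMFit, ga_grid) -> pd.DataFrame:
    """Estimated f_d(t) + alpha (group-1 minus group-0 Hb) with bands."""
    grid = np.atleast_1d(np.asarray(ga_grid, float))
    c1 = fit._design_row(grid, 1)
    c0 = fit._design_row(grid, 0)
    Cmat = c1 - c0
    diff = Cmat @ fit.theta_top
    var = np.einsum("ij,jk,ik->i", Cmat, fit.cov_top, Cmat)
    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {"ga_weeks": grid, "diff": diff,
         "lo": diff - Z975 * se, "hi": diff + Z975 * se}
    )


def run_gamm(cohort: CohortData, outcomes=("lbw", "ptb", "sga"),
             basis_dim: int = 5, grid_points: int = 50):
    """Full method 4: one stratified fit and trajectory pair per outcome."""
    results = {}
    for name in outcomes:
        try:
            fit = fit_gamm(cohort, name, basis_dim=basis_dim)
            grid = np.linspace(*fit.t_range, grid_points)
            results[name] = {
                "fit": fit,
                "trajectories": pd.concat(
                    [predict_trajectories(fit, grid, g) for g in (0, 1)],
                    ignore_index=True,
                ),
                "difference": difference_curve(fit, grid),
                "edf_difference": edf_of_difference(fit),
            }
        except EstimationError as exc:
            results[name] = {"error": exc}
    return results
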