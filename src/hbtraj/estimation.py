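"""Shared estimation machinery.

Ordinary least squares, logistic regression by iteratively reweighted
least squares (IRLS) with Wald inference and separation detection, a
linear mixed model fitted by profiled REML with per-subject blocks and
empirical-Bayes BLUPs, and a natural cubic spline basis.

The mixed-model fitter exploits the cohort structure (few observations
per subject) by evaluating the REML criterion blockwise, which makes the
hundreds of refits used in the Monte-Carlo calibration studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

Z975 = 1.959963984540054  # Phi^{-1}(0.975)


class EstimationError(RuntimeError):
    """Base class for estimation failures."""


class SingularDesignError(EstimationError):
    """Design matrix is rank deficient."""


class SeparationError(EstimationError):
    """Complete or quasi-complete separation in logistic regression."""


class ConvergenceError(EstimationError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Least-squares fit: named coefficients, residuals, residual SD."""

    coefficients: np.ndarray
    names: list
    residuals: np.ndarray
    residual_sd: float
    fitted: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


def fit_ols(X, y, names=None) -> LinearFit:
    """Ordinary least squares with an explicit rank check.

    Parameters
    ----------
    X : (n, p) array
        Design matrix including any intercept column.
    y : (n,) array
        Response.
    names : list of str, optional
        Column names; defaults to ``b0..b{p-1}``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(f"need more observations ({n}) than columns ({p})")
    if names is None:
        names = [f"b{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise SingularDesignError(f"design matrix rank {rank} < {p} columns")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sd = float(np.sqrt(resid @ resid / (n - p)))
    return LinearFit(beta, list(names), resid, sd, fitted)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Logistic MLE with Wald covariance and OR-scale reporting.

    ``scales`` maps coefficient name -> (multiplier, label); odds ratios
    are reported as exp(multiplier * beta), e.g. multiplier 5 for an OR
    per 5 g/L.
    """

    coefficients: np.ndarray
    names: list
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    scales: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sqrt(self.cov[j, j]))

    @property
    def aic(self) -> float:
        return 2.0 * len(self.coefficients) - 2.0 * self.loglik

    def or_table(self) -> pd.DataFrame:
        """Odds ratios with 95% Wald CIs on each coefficient's stated scale."""
        rows = []
        for j, name in enumerate(self.names):
            mult, label = self.scales.get(name, (1.0, "per 1 unit"))
            b = self.coefficients[j] * mult
            se = np.sqrt(self.cov[j, j]) * abs(mult)
            rows.append(
                {
                    "term": name,
                    "scale": label,
                    "or": np.exp(b),
                    "or_lo": np.exp(b - Z975 * se),
                    "or_hi": np.exp(b + Z975 * se),
                    "log_or": b,
                    "se_log_or": se,
                }
            )
        return pd.DataFrame(rows)

    def contrast_or(self, contrast):
        """OR, (lo, hi) for a linear contrast c'beta by the delta method."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.coefficients)
        se = float(np.sqrt(c @ self.cov @ c))
        return np.exp(est), (np.exp(est - Z975 * se), np.exp(est + Z975 * se))


def _logistic_loglik(X, y, beta):
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(X, y, names=None, max_iter=100, tol=1e-10, scales=None) -> LogisticFit:
    """Logistic-regression MLE by iteratively reweighted least squares.

    Raises
    ------
    EstimationError
        If the response has a single class.
    SeparationError
        When a standardized coefficient exceeds +-15 while the deviance is
        still decreasing, the classic footprint of (quasi-)separation; the
        error names the offending column.
    ConvergenceError
        After ``max_iter`` IRLS steps without meeting ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"b{j}" for j in range(p)]
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise EstimationError(f"response must be binary 0/1, got values {uniq[:5]}")
    if uniq.size < 2:
        raise EstimationError("one-class response: outcome has no variation")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(f"logistic design rank-deficient ({p} columns)")

    # column SDs for the standardized-scale separation check
    col_sd = X.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0  # intercept-like columns

    beta = np.zeros(p)
    ll = _logistic_loglik(X, y, beta)
    trace = [ll]
    prev_max_std = 0.0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        XtW = X.T * w
        info = XtW @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("information matrix singular in IRLS") from exc
        # step-halving to guarantee ascent
        new_beta, new_ll = beta + step, _logistic_loglik(X, y, beta + step)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _logistic_loglik(X, y, new_beta)
            halvings += 1
        improving = new_ll > ll + 1e-8 * (abs(ll) + 1.0)
        beta, prev_ll, ll = new_beta, ll, new_ll
        trace.append(ll)
        std_beta = beta * col_sd
        max_std = float(np.abs(std_beta).max())
        # separation: a coefficient beyond +-15 on the standardized scale
        # that keeps growing while the deviance is still decreasing and
        # fitted probabilities are collapsing to 0/1 (collinear designs can
        # hold large offsetting coefficients at an interior MLE)
        if improving and max_std > 15.0 and max_std > prev_max_std + 0.5:
            mu_now = expit(X @ beta)
            degenerate = np.mean((mu_now < 1e-6) | (mu_now > 1.0 - 1e-6))
            if degenerate > 0.01:
                j = int(np.argmax(np.abs(std_beta)))
                raise SeparationError(
                    f"separation detected: column {names[j]!r} has standardized "
                    f"coefficient {std_beta[j]:.1f} with deviance still decreasing"
                )
        prev_max_std = max_std
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace=trace
        )

    mu = expit(X @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    return LogisticFit(
        beta, list(names), cov, ll, it, True, scales=dict(scales or {})
    )


# ---------------------------------------------------------------------------
# Linear mixed model (profiled REML, blockwise)
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Linear mixed model fit.

    Fixed effects with Wald CIs; unstructured random-effect covariance
    ``re_cov`` (q x q); residual variance; per-subject BLUPs (empirical
    Bayes) as a DataFrame indexed by subject.
    """

    fixed_effects: np.ndarray
    fixed_names: list
    fixed_cov: np.ndarray
    re_cov: np.ndarray
    re_names: list
    sigma2: float
    blups: pd.DataFrame
    loglik_reml: float
    converged: bool
    boundary: bool

    def fixed_ci(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.fixed_cov))
        return pd.DataFrame(
            {
                "term": self.fixed_names,
                "estimate": self.fixed_effects,
                "lo": self.fixed_effects - Z975 * se,
                "hi": self.fixed_effects + Z975 * se,
            }
        )


def _chol_from_params(theta, q):
    """Lower-triangular Cholesky factor from an unconstrained vector.

    Diagonal entries are exp-transformed to stay positive.
    """
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(np.clip(theta[idx], -15.0, 15.0))
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


def _group_blocks(groups, X, Z, y):
    """Split rows into per-subject blocks, batched by block size."""
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    Xo, Zo, yo = X[order], Z[order], y[order]
    ids, starts, counts = np.unique(g, return_index=True, return_counts=True)
    batches = {}
    for size in np.unique(counts):
        sel = counts == size
        rows = (starts[sel][:, None] + np.arange(size)[None, :]).ravel()
        m = int(sel.sum())
        Zb = Zo[rows].reshape(m, size, -1)
        z_const = bool(np.all(Zb == Zb[:1]))
        batches[int(size)] = (
            ids[sel],
            Xo[rows].reshape(m, size, -1),
            Zb,
            yo[rows].reshape(m, size),
            z_const,
        )
    return batches


def _reml_pieces(batches, Psi, p):
    """Accumulate REML sufficient statistics across size-batched blocks.

    Returns (logdet_V, XtVX, XtVy, ytVy) for Vbar_i = I + Z_i Psi Z_i'.
    """
    logdet = 0.0
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    for size, (_ids, Xb, Zb, yb, z_const) in batches.items():
        m = Xb.shape[0]
        if z_const:
            # identical random design across the batch: one V suffices
            V1 = np.eye(size) + Zb[0] @ Psi @ Zb[0].T
            sign, ld = np.linalg.slogdet(V1)
            if sign <= 0:
                return None
            logdet += float(ld) * m
            Vinv1 = np.linalg.inv(V1)
            XtVi = np.transpose(Xb, (0, 2, 1)) @ Vinv1
            XtVX += np.einsum("mpk,mkq->pq", XtVi, Xb)
            XtVy += np.einsum("mpk,mk->p", XtVi, yb)
            ytVy += float(np.einsum("mk,kl,ml->", yb, Vinv1, yb))
            continue
        V = np.eye(size)[None] + Zb @ Psi @ np.transpose(Zb, (0, 2, 1))
        sign, ld = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            return None
        logdet += float(ld.sum())
        Vinv = np.linalg.inv(V)
        XtVi = np.transpose(Xb, (0, 2, 1)) @ Vinv
        XtVX += np.einsum("mpk,mkq->pq", XtVi, Xb)
        XtVy += np.einsum("mpk,mk->p", XtVi, yb)
        ytVy += float(np.einsum("mk,mkl,ml->", yb, Vinv, yb))
    return logdet, XtVX, XtVy, ytVy


def fit_lmm(X, Z, y, groups, fixed_names=None, re_names=None,
            max_iter=500, n_starts=3, seed=0, polish=True) -> LMMFit:
    """Linear mixed model y = X b + Z u_i + e by profiled REML.

    Random effects u_i ~ N(0, G) with unstructured covariance G, shared
    across subjects; residuals N(0, sigma2). The scaled covariance
    Psi = G / sigma2 is parameterized through its Cholesky factor and the
    REML criterion (with sigma2 profiled out) is minimized numerically;
    each evaluation runs blockwise over subjects so cohorts of a few
    thousand women fit in milliseconds.

    Parameters
    ----------
    X, Z : (n, p), (n, q) arrays
        Fixed and random-effect design matrices (rows aligned); the random
        design is typically a subset of the fixed columns.
    y : (n,) array
    groups : (n,) array
        Subject identifier per row.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    q = Z.shape[1]
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]
    if re_names is None:
        re_names = [f"u{j}" for j in range(q)]
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("fixed-effect design rank deficient")

    batches = _group_blocks(groups, X, Z, y)
    n_groups = sum(len(b[0]) for b in batches.values())
    if n <= p:
        raise SingularDesignError("more fixed-effect columns than observations")

    def neg2_reml(theta):
        Psi_L = _chol_from_params(theta, q)
        Psi = Psi_L @ Psi_L.T
        pieces = _reml_pieces(batches, Psi, p)
        if pieces is None:
            return 1e12
        logdet, XtVX, XtVy, ytVy = pieces
        try:
            c = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return 1e12
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta
        if rss <= 0:
            return 1e12
        sigma2 = rss / (n - p)
        return (
            logdet
            + 2.0 * np.log(np.diag(c)).sum()
            + (n - p) * np.log(sigma2)
        )

    ntheta = q * (q + 1) // 2
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        theta0 = np.zeros(ntheta)
        diag_idx = np.cumsum(np.arange(1, q + 1)) - 1
        theta0[diag_idx] = np.log(0.5 + s)  # growing start scale
        if s > 0:
            theta0 += 0.3 * rng.standard_normal(ntheta)
        res = optimize.minimize(
            neg2_reml, theta0, method="Nelder-Mead",
            options={"maxiter": max_iter * ntheta, "xatol": 1e-4, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed", trace=[])
    if polish:
        # tight polish from the winning start (simplex is already local)
        refined = optimize.minimize(
            neg2_reml, best.x, method="Nelder-Mead",
            options={"maxiter": 120 * ntheta, "xatol": 1e-9, "fatol": 1e-11},
        )
        if np.isfinite(refined.fun) and refined.fun <= best.fun:
            best = refined

    Psi_L = _chol_from_params(best.x, q)
    Psi = Psi_L @ Psi_L.T
    logdet, XtVX, XtVy, ytVy = _reml_pieces(batches, Psi, p)
    beta = np.linalg.solve(XtVX, XtVy)
    sigma2 = float((ytVy - XtVy @ beta) / (n - p))
    G = sigma2 * Psi
    fixed_cov = sigma2 * np.linalg.inv(XtVX)
    boundary = bool(np.any(np.diag(Psi) < 1e-8))

    # BLUPs: u_i = Psi Z_i' Vbar_i^{-1} (y_i - X_i beta)
    rows = []
    for size, (ids, Xb, Zb, yb, _zc) in batches.items():
        V = np.eye(size)[None] + Zb @ Psi @ np.transpose(Zb, (0, 2, 1))
        resid = yb - np.einsum("mkp,p->mk", Xb, beta)
        u = np.einsum(
            "qr,mkr,mkl,ml->mq", Psi, Zb, np.linalg.inv(V), resid
        )
        rows.append(pd.DataFrame(u, index=ids, columns=re_names))
    blups = pd.concat(rows).sort_index()
    blups.index.name = "subject_id"

    loglik_reml = -0.5 * (best.fun + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    return LMMFit(
        beta, list(fixed_names), fixed_cov, G, list(re_names), sigma2,
        blups, float(loglik_reml), bool(best.success or best.fun < 1e11), boundary,
    )


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Natural cubic spline basis (truncated-power construction).

    With m interior knots the basis has dimension m + 1 (no intercept);
    the basis functions are linear beyond the boundary knots. With zero
    interior knots the basis is just {x}.
    """

    interior_knots: np.ndarray
    boundary_knots: tuple

    def __post_init__(self):
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        lo, hi = self.boundary_knots
        knots = np.concatenate([[lo], self.interior_knots, [hi]])
        if np.any(np.diff(knots) <= 0):
            raise EstimationError(
                f"knots must be strictly increasing within the boundary, got {knots}"
            )
        self._knots = knots

    @property
    def dim(self) -> int:
        return len(self.interior_knots) + 1

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at x: returns an (len(x), dim) matrix."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = self._knots
        t = len(k)
        cols = [x]
        if t > 2:
            def d(j):
                return (
                    np.maximum(x - k[j], 0.0) ** 3
                    - np.maximum(x - k[t - 1], 0.0) ** 3
                ) / (k[t - 1] - k[j])

            d_last = d(t - 2)
            for j in range(t - 2):
                cols.append(d(j) - d_last)
        return np.column_stack(cols)

    def penalty(self, n_grid=2001) -> np.ndarray:
        """Second-derivative penalty matrix S = int B''(t) B''(t)' dt.

        Computed by composite trapezoid on a fine grid; exact up to grid
        error since the second derivatives are piecewise linear.
        """
        lo, hi = self.boundary_knots
        grid = np.linspace(lo, hi, n_grid)
        h = grid[1] - grid[0]
        B = self.evaluate(grid)
        d2 = (B[2:] - 2 * B[1:-1] + B[:-2]) / h**2
        w = np.full(len(d2), h)
        w[0] *= 0.5
        w[-1] *= 0.5
        return (d2 * w[:, None]).T @ d2


def natural_cubic_basis(x, interior_knots, boundary_knots):
    """Convenience wrapper: build the basis and evaluate it at x."""
    basis = SplineBasis(np.asarray(interior_knots, float), tuple(boundary_knots))
    return basis, basis.evaluate(x)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(values):
    """Center and scale to sample SD 1 (ddof=1).

    Returns (standardized, mean, sd). Raises on constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EstimationError("need at least 2 values to standardize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise EstimationError("constant input: standard deviation is zero")
    return (v - mean) / sd, mean, sd
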