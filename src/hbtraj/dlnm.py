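"""Method 3: distributed lag non-linear logistic model (DLNM).

Each woman's 3 sparse Hb measurements are expanded to a weekly exposure
profile on gestational weeks 1-39 (linear interpolation between visits,
constant extrapolation beyond them, with provenance recorded). A
cross-basis combines an exposure-dimension basis (linear or natural
cubic spline, centered at the 110 g/L reference so contrasts against the
reference are exact) with a lag-dimension basis over the weekly grid
(constant, linear, or natural spline). The outcome is fitted by logistic
regression on the cross-basis columns; candidate bases are compared by
AIC; the fitted surface is summarized as the per-week odds ratio of a
+5 g/L deviation from 110 g/L, with pointwise delta-method bands.

The gestational week is used directly as the lag index (lag = 39 - week
is the same axis relabeled), matching OR curves plotted against
gestational age.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CohortData
from .estimation import (
    EstimationError,
    LogisticFit,
    SplineBasis,
    Z975,
    fit_logistic,
)

logger = logging.getLogger(__name__)

WEEKS = np.arange(1, 40, dtype=float)  # weekly exposure grid, weeks 1-39
DEFAULT_REFERENCE = 110.0  # g/L
DEFAULT_INCREMENT = 5.0  # g/L


@dataclass
class ExposureProfiles:
    """Weekly Hb profiles: (n_subjects, 39) values plus provenance codes.

    Provenance per cell: ``"observed"`` (a visit fell in that week),
    ``"interpolated"`` (between visits) or ``"extrapolated"`` (before the
    first / after the last visit).
    """

    values: pd.DataFrame  # index subject_id, columns wk1..wk39
    provenance: pd.DataFrame
    excluded: list = field(default_factory=list)

    @property
    def subject_ids(self):
        return self.values.index.to_numpy()

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def build_exposure_profiles(cohort: CohortData) -> ExposureProfiles:
    """Linear interpolation / constant extrapolation onto weeks 1-39.

    Subjects with fewer than two distinct visit weeks cannot anchor an
    interpolation and are excluded with a logged message.
    """
    cols = [f"wk{int(w)}" for w in WEEKS]
    vals, provs, ids, excluded = [], [], [], []
    for sid, grp in cohort.visits.groupby("subject_id", sort=True):
        t = grp["ga_weeks"].to_numpy(dtype=float)
        x = grp["hb_g_l"].to_numpy(dtype=float)
        order = np.argsort(t)
        t, x = t[order], x[order]
        if np.unique(np.round(t, 6)).size < 2:
            excluded.append(sid)
            continue
        prof = np.interp(WEEKS, t, x)  # np.interp holds endpoints constant
        prov = np.where(
            WEEKS < t[0], "extrapolated",
            np.where(WEEKS > t[-1], "extrapolated", "interpolated"),
        ).astype(object)
        for tv in t:
            near = np.abs(WEEKS - tv) < 0.5
            prov[near] = "observed"
        ids.append(sid)
        vals.append(prof)
        provs.append(prov)
    if excluded:
        logger.info(
            "build_exposure_profiles: excluded %d subjects with <2 distinct "
            "visit weeks", len(excluded)
        )
    if not ids:
        raise EstimationError("no subject has >=2 distinct visit weeks")
    values = pd.DataFrame(vals, index=pd.Index(ids, name="subject_id"), columns=cols)
    provenance = pd.DataFrame(provs, index=values.index, columns=cols)
    return ExposureProfiles(values, provenance, excluded)


@dataclass
class CrossBasisSpec:
    """Exposure-dimension x lag-dimension basis definition.

    exposure_type: "linear" or "ns" (natural spline, ``exposure_knots``
    interior knots); the exposure basis is centered at ``reference`` so
    every column vanishes there. lag_type: "const", "linear" or "ns"
    (interior knots equally spaced over weeks 1-39).
    """

    exposure_type: str = "linear"
    exposure_knots: tuple = ()
    lag_type: str = "const"
    lag_knots: tuple = ()
    reference: float = DEFAULT_REFERENCE
    exposure_boundary: tuple = (70.0, 160.0)

    def label(self) -> str:
        ek = ",".join(f"{k:g}" for k in self.exposure_knots)
        lk = ",".join(f"{k:g}" for k in self.lag_knots)
        return f"exp={self.exposure_type}({ek})|lag={self.lag_type}({lk})"

    def exposure_design(self, hb: np.ndarray) -> np.ndarray:
        """Centered exposure basis: B(hb) - B(reference)."""
        if self.exposure_type == "linear":
            return (np.asarray(hb, float) - self.reference)[..., None]
        if self.exposure_type == "ns":
            basis = SplineBasis(np.asarray(self.exposure_knots, float),
                                self.exposure_boundary)
            flat = np.asarray(hb, float).ravel()
            B = basis.evaluate(flat) - basis.evaluate([self.reference])
            return B.reshape(np.shape(hb) + (basis.dim,))
        raise EstimationError(f"unknown exposure basis {self.exposure_type!r}")

    def lag_design(self) -> np.ndarray:
        """Lag basis evaluated on the weekly grid: (39, dl)."""
        if self.lag_type == "const":
            return np.ones((len(WEEKS), 1))
        if self.lag_type == "linear":
            return np.column_stack([np.ones(len(WEEKS)), WEEKS - WEEKS.mean()])
        if self.lag_type == "ns":
            basis = SplineBasis(np.asarray(self.lag_knots, float), (1.0, 39.0))
            return np.column_stack([np.ones(len(WEEKS)), basis.evaluate(WEEKS)])
        raise EstimationError(f"unknown lag basis {self.lag_type!r}")

    @property
    def dim(self) -> int:
        dx = 1 if self.exposure_type == "linear" else len(self.exposure_knots) + 1
        dl = {"const": 1, "linear": 2}.get(self.lag_type)
        if dl is None:
            dl = len(self.lag_knots) + 2
        return dx * dl


def build_cross_basis(profiles: ExposureProfiles, spec: CrossBasisSpec) -> np.ndarray:
    """Per-subject cross-basis rows: q[k,l] = sum_w Bexp_k(Hb_w) * Blag_l(w).

    Returns an (n_subjects, dx*dl) matrix aligned with profiles.subject_ids.
    """
    H = profiles.matrix()  # (n, 39)
    n = H.shape[0]
    E = spec.exposure_design(H)  # (n, 39, dx)
    L = spec.lag_design()  # (39, dl)
    Q = np.einsum("nwk,wl->nkl", E, L).reshape(n, -1)
    if Q.shape[1] >= n:
        raise EstimationError(
            f"cross-basis dimension {Q.shape[1]} exceeds the number of "
            f"subjects {n}: over-parameterized specification"
        )
    return Q


@dataclass
class DLNMFit:
    spec: CrossBasisSpec
    logistic: LogisticFit
    subject_ids: np.ndarray
    linear_predictor: np.ndarray

    @property
    def aic(self) -> float:
        return self.logistic.aic


def fit_dlnm(profiles: ExposureProfiles, outcome: pd.Series,
             spec: CrossBasisSpec) -> DLNMFit:
    """Constrained logistic fit on the cross-basis columns."""
    Q = build_cross_basis(profiles, spec)
    tab = pd.DataFrame(Q, index=profiles.values.index)
    tab = tab.join(outcome.rename("y"), how="inner").dropna()
    y = tab["y"].to_numpy(float)
    Qm = tab.drop(columns="y").to_numpy(float)
    X = np.column_stack([np.ones(len(tab)), Qm])
    names = ["intercept"] + [f"cb{j}" for j in range(Qm.shape[1])]
    fit = fit_logistic(X, y, names=names)
    return DLNMFit(spec, fit, tab.index.to_numpy(), X @ fit.coefficients)


def default_candidate_specs(profiles: ExposureProfiles):
    """Default AIC grid: exposure {linear, ns 2 or 3 knots at quantiles} x
    lag {const, linear, ns 2 equally spaced knots}."""
    H = profiles.matrix().ravel()
    specs = []
    exp_opts = [("linear", ())]
    for m in (2, 3):
        qs = np.quantile(H, np.linspace(0, 1, m + 2)[1:-1])
        specs_knots = tuple(np.round(qs, 2))
        exp_opts.append(("ns", specs_knots))
    lag_opts = [("const", ()), ("linear", ()), ("ns", (13.0, 26.0))]
    for (et, ek), (lt, lk) in itertools.product(exp_opts, lag_opts):
        specs.append(CrossBasisSpec(et, ek, lt, lk))
    return specs


def select_model_aic(profiles: ExposureProfiles, outcome: pd.Series,
                     candidate_specs=None):
    """Fit every candidate spec; return (best DLNMFit, AIC table).

    Ties are broken by smaller cross-basis dimension, then by the spec's
    lexical label. Failed fits are kept in the table with their error.
    """
    if candidate_specs is None:
        candidate_specs = default_candidate_specs(profiles)
    if len(candidate_specs) < 2:
        raise EstimationError("need at least 2 candidate specifications")
    rows, fits = [], {}
    for i, spec in enumerate(candidate_specs):
        try:
            fit = fit_dlnm(profiles, outcome, spec)
            rows.append(
                {"spec": spec.label(), "dim": spec.dim, "aic": fit.aic,
                 "loglik": fit.logistic.loglik, "status": "ok"}
            )
            fits[i] = fit
        except EstimationError as exc:
            rows.append(
                {"spec": spec.label(), "dim": spec.dim, "aic": np.nan,
                 "loglik": np.nan, "status": f"failed: {exc}"}
            )
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise EstimationError(
            "all candidate cross-basis specifications failed: "
            + "; ".join(table["status"])
        )
    best_idx = ok.sort_values(["aic", "dim", "spec"]).index[0]
    return fits[best_idx], table


def predict_or_curve(fit: DLNMFit, increment=DEFAULT_INCREMENT,
                     reference=None) -> pd.DataFrame:
    """Per-week OR of (reference + increment) vs reference, with 95% CI.

    The contrast at week w is the cross-basis row of a profile equal to
    reference everywhere except reference+increment at week w, minus the
    all-reference row; because the exposure basis is centered at the
    reference this reduces to Bexp(ref+increment) (x) Blag(w).
    """
    spec = fit.spec
    if reference is not None and abs(reference - spec.reference) > 1e-9:
        logger.warning(
            "requested reference %.1f differs from the basis centering %.1f; "
            "using the basis centering", reference, spec.reference
        )
    e = spec.exposure_design(np.array([spec.reference + increment]))[0]  # (dx,)
    L = spec.lag_design()  # (39, dl)
    beta = fit.logistic.coefficients[1:]
    cov = fit.logistic.cov[1:, 1:]
    rows = []
    for w, lrow in zip(WEEKS, L):
        c = np.outer(e, lrow).ravel()
        log_or = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        rows.append(
            {"week": w, "or": np.exp(log_or),
             "or_lo": np.exp(log_or - Z975 * se),
             "or_hi": np.exp(log_or + Z975 * se),
             "log_or": log_or, "se": se}
        )
    return pd.DataFrame(rows)


def run_dlnm(cohort: CohortData, outcomes=("lbw", "ptb", "sga"),
             candidate_specs=None, increment=DEFAULT_INCREMENT):
    """Full method 3 for each outcome: profiles, AIC selection, OR curve."""
    profiles = build_exposure_profiles(cohort)
    results = {}
    for name in outcomes:
        try:
            fit, table = select_model_aic(
                profiles, cohort.outcome_vector(name), candidate_specs
            )
            curve = predict_or_curve(fit, increment=increment)
            results[name] = {"fit": fit, "aic_table": table, "or_curve": curve}
        except EstimationError as exc:
            results[name] = {"error": exc}
    return profiles, results
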