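"""Synthetic pregnancy-cohort generator.

Emulates the statistical structure the five downstream methods assume:
2-3 antenatal visits per woman centered at gestational weeks 10/24/32,
hemoglobin built from trimester-level fixed effects (first-trimester mean
119.7 g/L, second and third trimester 8.7 and 6.25 g/L lower) plus
subject-level random intercepts and trimester slopes and Gaussian
measurement noise, optional latent trajectory classes or a smooth
U-shaped weekly exposure curve, and binary birth outcomes drawn from a
configurable logistic link (marginal prevalences near LBW 19%, PTB 6%,
SGA 31%).

Ground truth (random effects, class labels, linear predictors) is always
returned next to the data so recovery tests can score the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import CohortData, assign_trimester

#: Default marginal outcome prevalences (overall cohort, N=6452 scale).
DEFAULT_PREVALENCES = {"lbw": 0.186, "ptb": 0.064, "sga": 0.309}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Hb model (g/L): fixed trimester means (intercept + contrasts), subject
    random intercept and random trimester-2/3 slopes, iid noise. Visit
    times are triangular-jittered around ``visit_time_centers`` and
    truncated to stay inside the intended trimester. The random-effect SD
    defaults reproduce the precision of the trimester contrasts observed
    at n=676 in cohorts of this design.

    ``outcome_model``:
      * ``"null"`` -- logit(P) is the constant ``logit(prevalence)``;
      * ``"random_effect_link"`` -- logit(P) = c0 + c1*b0i + c2*b1i + c3*b2i
        with ``outcome_coefs[outcome] = (c0, c1, c2, c3)``;
      * ``"class_link"`` -- logit(P) = outcome_coefs[outcome][class_i].
    """

    n_subjects: int = 6452
    prop_three_visits: float = 676 / 6452
    fixed_intercept: float = 119.7
    effect_t2: float = -8.7
    effect_t3: float = -6.25
    sd_random_intercept: float = 11.0
    sd_random_slope_t2: float = 9.5
    sd_random_slope_t3: float = 9.5
    sd_noise: float = 8.0
    visit_time_centers: tuple = (10.0, 24.0, 32.0)
    visit_time_jitter: float = 2.0
    outcome_model: str = "null"
    outcome_coefs: dict = field(default_factory=dict)
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    n_classes: int = 1
    class_proportions: tuple = (1.0,)
    class_polynomials: tuple = ()
    u_shape: bool = False
    u_shape_nadir_week: float = 24.0
    u_shape_curvature: float = 0.03
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if not (0.0 <= self.prop_three_visits <= 1.0):
            raise ValueError("prop_three_visits must lie in [0, 1]")
        for name in ("sd_random_intercept", "sd_random_slope_t2",
                     "sd_random_slope_t3", "sd_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_classes > 1:
            props = np.asarray(self.class_proportions, float)
            if len(props) != self.n_classes or abs(props.sum() - 1.0) > 1e-8:
                raise ValueError("class_proportions must have length n_classes and sum to 1")
            if len(self.class_polynomials) != self.n_classes:
                raise ValueError("class_polynomials must have one entry per class")
        if self.outcome_model not in {"null", "random_effect_link", "class_link"}:
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")


#: Trimester window for each visit slot (visit 1 -> trimester 1, ...).
_VISIT_TRIMESTER_BOUNDS = ((0.5, 12.9), (13.1, 28.9), (29.1, 40.5))


def _draw_visit_times(rng, centers, jitter, slots):
    """Triangular jitter around each slot's center, truncated to its trimester."""
    times = np.empty(len(slots))
    for i, s in enumerate(slots):
        c = centers[s]
        lo, hi = _VISIT_TRIMESTER_BOUNDS[s]
        t = rng.triangular(c - jitter, c, c + jitter)
        times[i] = min(max(t, lo), hi)
    return times


def _mean_hb(cfg, t, tri, class_label):
    """Population-mean Hb at time t (weeks) for the given class."""
    if cfg.n_classes > 1:
        coefs = np.asarray(cfg.class_polynomials[class_label], float)
        return np.polyval(coefs[::-1], t)  # coefs are (c0, c1, c2, ...)
    if cfg.u_shape:
        nadir = cfg.fixed_intercept + cfg.effect_t2
        return nadir + cfg.u_shape_curvature * (t - cfg.u_shape_nadir_week) ** 2
    contrast = {1: 0.0, 2: cfg.effect_t2, 3: cfg.effect_t3}[tri]
    return cfg.fixed_intercept + contrast


def _draw_outcome_lp(cfg, rng, b, class_labels):
    """Linear predictor (logit) per subject for each outcome."""
    n = b.shape[0]
    lps = {}
    for outcome, prev in cfg.prevalences.items():
        if cfg.outcome_model == "null" or outcome not in cfg.outcome_coefs:
            lps[outcome] = np.full(n, _logit(prev))
        elif cfg.outcome_model == "random_effect_link":
            c = np.asarray(cfg.outcome_coefs[outcome], float)
            lps[outcome] = c[0] + b @ c[1:4]
        else:  # class_link
            c = np.asarray(cfg.outcome_coefs[outcome], float)
            lps[outcome] = c[class_labels]
    return lps


def _continuous_from_flags(rng, lbw, ptb, sga):
    """Continuous delivery measurements consistent with the binary flags.

    Synthetic stand-ins: birthweight and delivery week are drawn from
    simple truncated distributions on the correct side of each cutoff;
    the SGA percentile is uniform on the matching side of 10.
    """
    n = len(lbw)
    bw = np.where(
        lbw == 1,
        rng.normal(2200.0, 180.0, n).clip(1200.0, 2499.0),
        rng.normal(3100.0, 350.0, n).clip(2500.0, 4800.0),
    )
    gad = np.where(
        ptb == 1,
        rng.uniform(30.0, 36.9, n),
        rng.uniform(37.0, 41.0, n),
    )
    pct = np.where(sga == 1, rng.uniform(0.0, 9.99, n), rng.uniform(10.0, 100.0, n))
    return bw.round(0), gad.round(1), pct.round(2)


def simulate_cohort(config: SimConfig):
    """Draw a cohort plus its ground truth.

    Returns
    -------
    (CohortData, pandas.DataFrame)
        The cohort and a per-subject ground-truth table with random
        effects ``b0/b1/b2`` (intercept, trimester-2 and trimester-3
        deviations, g/L), ``class_label``, ``n_visits`` and the outcome
        linear predictors ``lp_<outcome>``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subject_ids = np.arange(1, n + 1)

    three = rng.random(n) < cfg.prop_three_visits
    if cfg.n_classes > 1:
        class_labels = rng.choice(
            cfg.n_classes, size=n, p=np.asarray(cfg.class_proportions, float)
        )
    else:
        class_labels = np.zeros(n, dtype=int)

    b = np.column_stack(
        [
            rng.normal(0.0, cfg.sd_random_intercept, n),
            rng.normal(0.0, cfg.sd_random_slope_t2, n),
            rng.normal(0.0, cfg.sd_random_slope_t3, n),
        ]
    )

    rows = []
    for i in range(n):
        if three[i]:
            slots = (0, 1, 2)
        else:
            # enrollment in the first or second trimester plus an
            # end-of-gestation visit, as in the observed 2-visit pattern
            slots = (int(rng.integers(0, 2)), 2)
        times = _draw_visit_times(rng, cfg.visit_time_centers, cfg.visit_time_jitter, slots)
        for s, t in zip(slots, times):
            tri = assign_trimester(t)
            mu = _mean_hb(cfg, t, tri, class_labels[i])
            re = b[i, 0] + (b[i, 1] if tri == 2 else 0.0) + (b[i, 2] if tri == 3 else 0.0)
            hb = mu + re + rng.normal(0.0, cfg.sd_noise)
            rows.append((subject_ids[i], t, hb))
    visits = pd.DataFrame(rows, columns=["subject_id", "ga_weeks", "hb_g_l"])
    visits["hb_g_l"] = visits["hb_g_l"].clip(40.0, 200.0)

    lps = _draw_outcome_lp(cfg, rng, b, class_labels)
    flags = {k: (rng.random(n) < _expit(v)).astype(int) for k, v in lps.items()}
    bw, gad, pct = _continuous_from_flags(rng, flags["lbw"], flags["ptb"], flags["sga"])
    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "birthweight_g": bw,
            "ga_delivery_weeks": gad,
            "weight_percentile": pct,
            "lbw": pd.array(flags["lbw"], dtype="Int64"),
            "ptb": pd.array(flags["ptb"], dtype="Int64"),
            "sga": pd.array(flags["sga"], dtype="Int64"),
        }
    )

    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "b0": b[:, 0],
            "b1": b[:, 1],
            "b2": b[:, 2],
            "class_label": class_labels,
            "n_visits": np.where(three, 3, 2),
            **{f"lp_{k}": v for k, v in lps.items()},
        }
    )
    meta = {"seed": cfg.seed, "config": asdict(cfg)}
    return CohortData(visits, outcomes, meta), truth


def simulate_group_shift_cohort(
    config: SimConfig,
    shift_g_l: float = -5.0,
    before_week: float = 20.0,
    outcome: str = "ptb",
    prevalence: float | None = None,
):
    """Cohort where one outcome group's Hb is shifted early in gestation.

    The outcome label is drawn first (independently of Hb, at the stated
    prevalence); women with the outcome then have their mean Hb shifted by
    ``shift_g_l`` strictly before ``before_week`` and not after. This is
    the reverse-model fixture: a trajectory-difference method should see
    the groups separate early in gestation only.
    """
    cfg = config
    cfg.validate()
    if prevalence is None:
        prevalence = cfg.prevalences.get(outcome, 0.1)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subject_ids = np.arange(1, n + 1)
    y = (rng.random(n) < prevalence).astype(int)
    b0 = rng.normal(0.0, cfg.sd_random_intercept, n)
    nadir = cfg.fixed_intercept + cfg.effect_t2

    three = rng.random(n) < cfg.prop_three_visits
    rows = []
    for i in range(n):
        slots = (0, 1, 2) if three[i] else (int(rng.integers(0, 2)), 2)
        times = _draw_visit_times(rng, cfg.visit_time_centers,
                                  cfg.visit_time_jitter, slots)
        for t in times:
            mu = nadir + cfg.u_shape_curvature * (t - cfg.u_shape_nadir_week) ** 2
            if y[i] and t < before_week:
                mu += shift_g_l
            rows.append((subject_ids[i], t, mu + b0[i] + rng.normal(0.0, cfg.sd_noise)))
    visits = pd.DataFrame(rows, columns=["subject_id", "ga_weeks", "hb_g_l"])
    visits["hb_g_l"] = visits["hb_g_l"].clip(40.0, 200.0)

    flags = {k: (rng.random(n) < p).astype(int)
             for k, p in cfg.prevalences.items() if k != outcome}
    flags[outcome] = y
    bw, gad, pct = _continuous_from_flags(rng, flags["lbw"], flags["ptb"], flags["sga"])
    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "birthweight_g": bw,
            "ga_delivery_weeks": gad,
            "weight_percentile": pct,
            "lbw": pd.array(flags["lbw"], dtype="Int64"),
            "ptb": pd.array(flags["ptb"], dtype="Int64"),
            "sga": pd.array(flags["sga"], dtype="Int64"),
        }
    )
    truth = pd.DataFrame({"subject_id": subject_ids, "b0": b0, "y": y})
    meta = {"seed": cfg.seed, "shift_g_l": shift_g_l,
            "before_week": before_week, "outcome": outcome}
    return CohortData(visits, outcomes, meta), truth


def simulate_window_effect_cohort(
    config: SimConfig,
    effect_window=(30.0, 39.0),
    effect_per_5g=0.0,
    outcome="sga",
    base_prevalence=None,
):
    """Cohort whose outcome depends on Hb only inside a gestational window.

    Each woman gets a smooth latent weekly Hb curve on weeks 1-39
    (population U-shape plus a subject random intercept and a small
    random linear drift); the outcome's log-odds shift by
    ``effect_per_5g`` per 5 g/L of her mean centered latent Hb inside
    ``effect_window``. The observed data are 3 noisy visits sampled from
    the curve, so a distributed-lag analysis must reconstruct the window.

    Returns
    -------
    (CohortData, pandas.DataFrame, pandas.DataFrame)
        Cohort, ground-truth table (window exposure and outcome linear
        predictor), and the latent weekly curves (subjects x weeks 1-39).
    """
    cfg = config
    cfg.validate()
    lo, hi = float(effect_window[0]), float(effect_window[1])
    if not (1.0 <= lo <= hi <= 39.0):
        raise ValueError(f"effect window [{lo}, {hi}] must be non-empty inside weeks 1-39")
    if base_prevalence is None:
        base_prevalence = cfg.prevalences.get(outcome, 0.15)

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subject_ids = np.arange(1, n + 1)
    weeks = np.arange(1, 40, dtype=float)

    nadir = cfg.fixed_intercept + cfg.effect_t2
    pop = nadir + cfg.u_shape_curvature * (weeks - cfg.u_shape_nadir_week) ** 2
    b0 = rng.normal(0.0, cfg.sd_random_intercept, n)
    drift = rng.normal(0.0, 0.2, n)  # g/L per week, keeps curves smooth
    curves = pop[None, :] + b0[:, None] + drift[:, None] * (weeks - 24.0)[None, :]

    in_win = (weeks >= lo) & (weeks <= hi)
    exposure = curves[:, in_win].mean(axis=1)
    centered = exposure - exposure.mean()
    lp = _logit(base_prevalence) + (effect_per_5g / 5.0) * centered
    y = (rng.random(n) < _expit(lp)).astype(int)

    rows = []
    for i in range(n):
        times = _draw_visit_times(
            rng, cfg.visit_time_centers, cfg.visit_time_jitter, (0, 1, 2)
        )
        for t in times:
            hb = np.interp(t, weeks, curves[i]) + rng.normal(0.0, cfg.sd_noise)
            rows.append((subject_ids[i], t, hb))
    visits = pd.DataFrame(rows, columns=["subject_id", "ga_weeks", "hb_g_l"])
    visits["hb_g_l"] = visits["hb_g_l"].clip(40.0, 200.0)

    flags = {
        k: (rng.random(n) < p).astype(int)
        for k, p in cfg.prevalences.items()
        if k != outcome
    }
    flags[outcome] = y
    bw, gad, pct = _continuous_from_flags(rng, flags["lbw"], flags["ptb"], flags["sga"])
    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "birthweight_g": bw,
            "ga_delivery_weeks": gad,
            "weight_percentile": pct,
            "lbw": pd.array(flags["lbw"], dtype="Int64"),
            "ptb": pd.array(flags["ptb"], dtype="Int64"),
            "sga": pd.array(flags["sga"], dtype="Int64"),
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "b0": b0,
            "drift": drift,
            "window_exposure": exposure,
            f"lp_{outcome}": lp,
        }
    )
    curve_df = pd.DataFrame(curves, index=subject_ids, columns=[f"wk{int(w)}" for w in weeks])
    curve_df.index.name = "subject_id"
    meta = {
        "seed": cfg.seed,
        "window": (lo, hi),
        "effect_per_5g": effect_per_5g,
        "outcome": outcome,
    }
    return CohortData(visits, outcomes, meta), truth, curve_df
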