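"""Core data containers and preprocessing for repeated maternal hemoglobin data.

The study design: each woman contributes 2-3 hemoglobin (Hb, g/L)
measurements during pregnancy, indexed by gestational age in weeks, and a
set of binary birth outcomes (low birth weight, preterm birth,
small-for-gestational-age). Before any model is fitted, visits are mapped
to trimesters, multiple measurements within one trimester are averaged,
and per-outcome missingness is resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Trimester boundaries in gestational weeks. Intervals are half-open
#: [0, 13), [13, 29), [29, 41] so that the mapping is a function.
TRIMESTER_EDGES = (0.0, 13.0, 29.0, 41.0)

GA_MAX_WEEKS = 41.0

#: Plausibility range for Hb in g/L (guards against g/dL inputs).
HB_PLAUSIBLE_RANGE = (40.0, 200.0)

VISIT_COLUMNS = ["subject_id", "ga_weeks", "hb_g_l"]
OUTCOME_NAMES = ["lbw", "ptb", "sga"]


class CohortError(ValueError):
    """Raised for structurally invalid cohort data."""


class EmptyCohortError(CohortError):
    """Raised when a subsetting operation yields no subjects."""


def assign_trimester(ga_weeks):
    """Map gestational age (weeks) to trimester 1, 2 or 3.

    Uses half-open intervals [0, 13), [13, 29), [29, 41]; week 13 is
    second trimester, week 29 is third.

    Parameters
    ----------
    ga_weeks : float or array-like
        Gestational age in weeks; must lie in [0, 41].

    Returns
    -------
    int or ndarray of int
        Trimester in {1, 2, 3}, scalar when input is scalar.
    """
    arr = np.asanyarray(ga_weeks, dtype=float)
    bad = (arr < 0) | (arr > GA_MAX_WEEKS) | ~np.isfinite(arr)
    if np.any(bad):
        offending = arr[bad].ravel()[0] if arr.ndim else float(arr)
        raise CohortError(
            f"gestational age {offending} weeks outside the supported "
            f"range [0, {GA_MAX_WEEKS:g}]"
        )
    tri = np.digitize(arr, TRIMESTER_EDGES[1:3], right=False) + 1
    if arr.ndim == 0:
        return int(tri)
    return tri.astype(int)


def derive_outcomes(birthweight_g=None, ga_delivery_weeks=None, weight_percentile=None):
    """Derive the three binary birth outcomes from delivery measurements.

    lbw = birthweight < 2500 g; ptb = delivery before 37 weeks (strict);
    sga = birthweight percentile < 10 (simplified percentile rule).
    A missing input yields pandas.NA for that outcome, never a silent 0.

    Returns
    -------
    tuple (lbw, ptb, sga)
        Each entry is 0, 1 or :data:`pandas.NA`.
    """

    def _flag(value, threshold, low, high, label):
        if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
            return pd.NA
        v = float(value)
        if not (low <= v <= high):
            raise CohortError(f"{label}={v} outside plausible range [{low}, {high}]")
        return int(v < threshold)

    lbw = _flag(birthweight_g, 2500.0, 200.0, 8000.0, "birthweight_g")
    ptb = _flag(ga_delivery_weeks, 37.0, 20.0, 45.0, "ga_delivery_weeks")
    sga = _flag(weight_percentile, 10.0, 0.0, 100.0, "weight_percentile")
    return lbw, ptb, sga


@dataclass
class CohortData:
    """Long-format repeated-measures container.

    Attributes
    ----------
    visits : pandas.DataFrame
        One row per Hb measurement: ``subject_id``, ``ga_weeks``,
        ``hb_g_l`` and, once assigned, ``trimester``.
    outcomes : pandas.DataFrame
        One row per subject: ``subject_id``, optional ``birthweight_g``,
        ``ga_delivery_weeks``, ``weight_percentile`` and the binary
        columns ``lbw``, ``ptb``, ``sga`` (nullable).
    """

    visits: pd.DataFrame
    outcomes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise CohortError(f"visit table lacks required columns {missing}")
        if "subject_id" not in self.outcomes.columns:
            raise CohortError("outcome table lacks subject_id")
        visit_ids = set(self.visits["subject_id"])
        outcome_ids = set(self.outcomes["subject_id"])
        orphans = visit_ids - outcome_ids
        if orphans:
            raise CohortError(
                f"{len(orphans)} subjects have visits but no outcome row "
                f"(e.g. {sorted(orphans)[:3]})"
            )
        if self.outcomes["subject_id"].duplicated().any():
            raise CohortError("duplicate subject_id in outcome table")
        hb = self.visits["hb_g_l"].to_numpy(dtype=float)
        lo, hi = HB_PLAUSIBLE_RANGE
        if np.any((hb < lo) | (hb > hi)):
            raise CohortError(
                f"hb_g_l outside plausible range [{lo}, {hi}] g/L -- "
                "check units (g/dL vs g/L)"
            )

    @property
    def n_subjects(self) -> int:
        return self.visits["subject_id"].nunique()

    def visit_counts(self) -> pd.Series:
        """Number of Hb measurements per subject (ni), indexed by subject."""
        return self.visits.groupby("subject_id", sort=True).size()

    def with_trimesters(self) -> "CohortData":
        """Return a copy whose visits carry a ``trimester`` column."""
        v = self.visits.copy()
        v["trimester"] = assign_trimester(v["ga_weeks"].to_numpy())
        return CohortData(v, self.outcomes.copy(), dict(self.meta))

    def derive_missing_outcomes(self) -> "CohortData":
        """Fill lbw/ptb/sga from the continuous columns where absent."""
        out = self.outcomes.copy()
        for name in OUTCOME_NAMES:
            if name not in out.columns:
                out[name] = pd.NA
        sources = {
            "lbw": ("birthweight_g", 2500.0),
            "ptb": ("ga_delivery_weeks", 37.0),
            "sga": ("weight_percentile", 10.0),
        }
        for name, (src, cut) in sources.items():
            if src not in out.columns:
                continue
            vals = pd.to_numeric(out[src], errors="coerce")
            derived = pd.array(
                np.where(vals.notna(), (vals < cut).astype("float"), np.nan)
            )
            need = out[name].isna() & vals.notna()
            out.loc[need, name] = pd.array(derived[need.to_numpy()]).astype("float")
        for name in OUTCOME_NAMES:
            out[name] = out[name].astype("Float64").astype("Int64")
        return CohortData(self.visits.copy(), out, dict(self.meta))

    def outcome_vector(self, outcome: str) -> pd.Series:
        """Binary outcome indexed by subject_id, missing values dropped."""
        if outcome not in OUTCOME_NAMES:
            raise CohortError(f"unknown outcome {outcome!r}; expected one of {OUTCOME_NAMES}")
        s = self.outcomes.set_index("subject_id")[outcome].dropna()
        return s.astype(int)


def collapse_within_trimester(cohort: CohortData) -> CohortData:
    """Average multiple measurements within one (subject, trimester).

    Per-trimester Hb is the arithmetic mean of the originals; the collapsed
    visit time is the mean of the original times. Subjects' visit counts ni
    are implicitly recomputed. A no-op when no duplicates exist.
    """
    if "trimester" not in cohort.visits.columns:
        raise CohortError("trimester not assigned; call with_trimesters() first")
    g = cohort.visits.groupby(["subject_id", "trimester"], as_index=False, sort=True)
    collapsed = g.agg(ga_weeks=("ga_weeks", "mean"), hb_g_l=("hb_g_l", "mean"))
    collapsed = collapsed[["subject_id", "ga_weeks", "hb_g_l", "trimester"]]
    meta = dict(cohort.meta)
    meta["collapsed_rows"] = len(cohort.visits) - len(collapsed)
    return CohortData(collapsed.reset_index(drop=True), cohort.outcomes.copy(), meta)


def subset_by_visit_count(cohort: CohortData, k: int) -> CohortData:
    """Retain exactly the subjects with ni == k measurements."""
    ni = cohort.visit_counts()
    keep = set(ni.index[ni == k])
    logger.info(
        "subset_by_visit_count: k=%d retains %d of %d subjects", k, len(keep), len(ni)
    )
    if not keep:
        raise EmptyCohortError(f"no subjects with exactly {k} measurements")
    v = cohort.visits[cohort.visits["subject_id"].isin(keep)].reset_index(drop=True)
    o = cohort.outcomes[cohort.outcomes["subject_id"].isin(keep)].reset_index(drop=True)
    meta = dict(cohort.meta)
    meta["visit_count_filter"] = k
    return CohortData(v, o, meta)


def preprocess(cohort: CohortData) -> CohortData:
    """Full preprocessing chain: trimesters, outcome derivation, collapsing.

    Idempotent on its own output.
    """
    return collapse_within_trimester(cohort.with_trimesters().derive_missing_outcomes())


def read_cohort_csv(visits_path, subjects_path) -> CohortData:
    """Read the long visit CSV and the per-subject outcome CSV."""
    visits = pd.read_csv(visits_path)
    outcomes = pd.read_csv(subjects_path)
    for name in OUTCOME_NAMES:
        if name in outcomes.columns:
            outcomes[name] = pd.array(outcomes[name], dtype="Int64")
    return CohortData(visits, outcomes)


def write_cohort_csv(cohort: CohortData, visits_path, subjects_path) -> None:
    cohort.visits.to_csv(visits_path, index=False)
    cohort.outcomes.to_csv(subjects_path, index=False)


def trimester_wide(cohort: CohortData) -> pd.DataFrame:
    """Pivot a collapsed 3-visit cohort to one row per subject.

    Returns columns x1, x2, x3 (Hb by trimester) and t1, t2, t3 (times),
    indexed by subject_id. Requires exactly one measurement per trimester.
    """
    v = cohort.visits
    if "trimester" not in v.columns:
        raise CohortError("trimester not assigned")
    counts = v.groupby("subject_id").size()
    if not (counts == 3).all():
        raise CohortError("trimester_wide requires exactly 3 visits per subject")
    hb = v.pivot(index="subject_id", columns="trimester", values="hb_g_l")
    tt = v.pivot(index="subject_id", columns="trimester", values="ga_weeks")
    if hb.isna().any().any():
        raise CohortError("some subject lacks a measurement in one trimester")
    wide = pd.DataFrame(
        {
            "x1": hb[1], "x2": hb[2], "x3": hb[3],
            "t1": tt[1], "t2": tt[2], "t3": tt[3],
        }
    )
    return wide.sort_index()
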