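"""Run configuration, pipeline orchestration and reporting.

Ties the five methods into one reproducible pipeline: simulate (or load)
a cohort, preprocess it, run the requested methods on the appropriate
subsets (the additive mixed model on the full cohort; the residual,
two-stage, distributed-lag and trajectory-mixture methods on the
3-visit subset), and write per-method results JSON, figures and a run
manifest carrying the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dlnm as dlnm_mod
from . import gamm as gamm_mod
from . import gbtm as gbtm_mod
from . import residuals as residual_mod
from . import two_stage as two_stage_mod
from .data_model import (
    CohortData,
    preprocess,
    read_cohort_csv,
    subset_by_visit_count,
    write_cohort_csv,
)
from .estimation import EstimationError
from .synthetic import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_METHODS = ("residual", "two_stage", "dlnm", "gamm", "gbtm")
ALL_OUTCOMES = ("lbw", "ptb", "sga")

#: Methods fitted on the 3-visit subset (the rest use the full cohort).
THREE_VISIT_METHODS = {"residual", "two_stage", "dlnm", "gbtm"}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    methods: tuple = ALL_METHODS
    outcomes: tuple = ALL_OUTCOMES
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    method_options: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ConfigError(f"unknown methods {sorted(bad)}; expected {ALL_METHODS}")
        bad = set(self.outcomes) - set(ALL_OUTCOMES)
        if bad:
            raise ConfigError(f"unknown outcomes {sorted(bad)}; expected {ALL_OUTCOMES}")
        if not self.methods or not self.outcomes:
            raise ConfigError("need at least one method and one outcome")
        sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(self.simulation) - sim_keys
        if bad:
            raise ConfigError(f"unknown simulation config keys {sorted(bad)}")
        bad = set(self.method_options) - set(ALL_METHODS)
        if bad:
            raise ConfigError(f"unknown method_options keys {sorted(bad)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys {sorted(bad)}; expected {sorted(known)}")
        for key in ("methods", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path, config: RunConfig):
    obj = dict(obj)
    obj["seed"] = config.seed
    obj["config_hash"] = config.config_hash()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
    tmp.replace(path)


def cmd_simulate(config: RunConfig, out_dir) -> dict:
    """Generate a cohort and write visit/subject/ground-truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(config.sim_config())
    write_cohort_csv(cohort, out / "visits.csv", out / "subjects.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)
    manifest = {
        "n_subjects": int(cohort.n_subjects),
        "n_visits": int(len(cohort.visits)),
        "files": ["visits.csv", "subjects.csv", "ground_truth.csv"],
    }
    _write_json(manifest, out / "manifest.json", config)
    logger.info("simulated %d subjects (%d visits) into %s",
                cohort.n_subjects, len(cohort.visits), out)
    return manifest


def _or_table_payload(fit) -> dict:
    return {"or_table": fit.or_table().to_dict(orient="records"),
            "loglik": fit.loglik, "converged": fit.converged}


def _run_one_method(method, full, three, config: RunConfig):
    """Run one method; returns a JSON-ready payload."""
    opts = dict(config.method_options.get(method, {}))
    outcomes = config.outcomes
    if method == "residual":
        _, fits = residual_mod.run_residual_method(three, outcomes)
        return {"n_subjects": int(three.n_subjects),
                "per_outcome": {k: (_or_table_payload(v) if not isinstance(v, Exception)
                                    else {"error": str(v)})
                                for k, v in fits.items()}}
    if method == "two_stage":
        res = two_stage_mod.run_two_stage(three, outcomes, seed=config.seed)
        return {
            "n_subjects": int(three.n_subjects),
            "stage1": res.stage1.fixed_ci().to_dict(orient="records"),
            "stage1_sigma2": res.stage1.sigma2,
            "per_outcome": {k: (_or_table_payload(v) if not isinstance(v, Exception)
                                else {"error": str(v)})
                            for k, v in res.stage2.items()},
        }
    if method == "dlnm":
        _, results = dlnm_mod.run_dlnm(three, outcomes, **opts)
        payload = {"n_subjects": int(three.n_subjects), "per_outcome": {}}
        for k, r in results.items():
            if "error" in r:
                payload["per_outcome"][k] = {"error": str(r["error"])}
            else:
                payload["per_outcome"][k] = {
                    "best_spec": r["fit"].spec.label(),
                    "aic_table": r["aic_table"].to_dict(orient="records"),
                    "or_curve": r["or_curve"].to_dict(orient="records"),
                }
        return payload
    if method == "gamm":
        results = gamm_mod.run_gamm(full, outcomes, **opts)
        payload = {"n_subjects": int(full.n_subjects), "per_outcome": {}}
        for k, r in results.items():
            if "error" in r:
                payload["per_outcome"][k] = {"error": str(r["error"])}
            else:
                payload["per_outcome"][k] = {
                    "edf_difference": r["edf_difference"],
                    "edf_shared": r["fit"].edf_shared,
                    "sigma2": r["fit"].sigma2,
                    "sigma2_subject": r["fit"].sigma2_b,
                    "trajectories": r["trajectories"].to_dict(orient="records"),
                }
        return payload
    if method == "gbtm":
        res = gbtm_mod.run_gbtm(three, outcomes, seed=config.seed,
                                **{k: v for k, v in opts.items() if k == "n_restarts"})
        fit = res["fit"]
        return {
            "n_subjects": int(three.n_subjects),
            "selected_K": fit.n_classes,
            "degree": fit.degree,
            "proportions": fit.proportions.tolist(),
            "avg_max_posterior": float(res["assignments"]["max_posterior"].mean()),
            "selection_table": res["selection_table"].to_dict(orient="records"),
            "per_outcome": {k: (_or_table_payload(v) if not isinstance(v, Exception)
                                else {"error": str(v)})
                            for k, v in res["outcome_fits"].items()},
        }
    raise ConfigError(f"unknown method {method!r}")


def cmd_fit(config: RunConfig, data_dir, out_dir, make_figures=True) -> dict:
    """Run the requested methods on a cohort directory; write results JSON.

    A failing method is reported and skipped; raises only if every
    requested method fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(Path(data_dir) / "visits.csv",
                             Path(data_dir) / "subjects.csv")
    for name in config.outcomes:
        if name not in cohort.outcomes.columns or cohort.outcomes[name].isna().all():
            raise ConfigError(f"requested outcome {name!r} missing from the subject table")
    full = preprocess(cohort)
    three = subset_by_visit_count(full, 3)
    logger.info("cohort: %d subjects total, %d with 3 trimester values",
                full.n_subjects, three.n_subjects)

    summary = {"methods": {}, "n_full": int(full.n_subjects),
               "n_three_visit": int(three.n_subjects)}
    n_failed = 0
    for method in config.methods:
        t0 = time.perf_counter()
        try:
            payload = _run_one_method(method, full, three, config)
            payload["n_used"] = (summary["n_three_visit"]
                                 if method in THREE_VISIT_METHODS
                                 else summary["n_full"])
            payload["elapsed_s"] = round(time.perf_counter() - t0, 3)
            _write_json(payload, out / f"{method}.json", config)
            summary["methods"][method] = {"status": "ok",
                                          "n_used": payload["n_used"],
                                          "elapsed_s": payload["elapsed_s"]}
            if make_figures:
                try:
                    _make_figure(method, payload, out)
                except Exception as exc:  # figures are advisory
                    logger.warning("figure for %s failed: %s", method, exc)
        except (EstimationError, ConfigError) as exc:
            n_failed += 1
            logger.error("method %s failed: %s", method, exc)
            summary["methods"][method] = {"status": f"failed: {exc}"}
    _write_json(summary, out / "run_summary.json", config)
    if n_failed == len(config.methods):
        raise EstimationError("all requested methods failed; see run_summary.json")
    return summary


def _make_figure(method, payload, out_dir):
    """Advisory figures for the three curve-producing methods."""
    if method not in ("dlnm", "gamm", "gbtm"):
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if method == "gbtm":
        fig, ax = plt.subplots(figsize=(6, 4))
        # redraw class mean curves from the stored polynomial-free payload
        ax.bar(range(1, len(payload["proportions"]) + 1), payload["proportions"])
        ax.set_xlabel("trajectory class (canonical order)")
        ax.set_ylabel("mixing proportion")
        fig.savefig(Path(out_dir) / "gbtm.png", dpi=120)
        plt.close(fig)
        return
    per = payload["per_outcome"]
    fig, axes = plt.subplots(1, len(per), figsize=(4 * len(per), 3.2), squeeze=False)
    for ax, (name, r) in zip(axes[0], per.items()):
        if "error" in r:
            ax.set_title(f"{name}: failed")
            continue
        if method == "dlnm":
            curve = pd.DataFrame(r["or_curve"])
            ax.plot(curve["week"], curve["or"], color="k")
            ax.fill_between(curve["week"], curve["or_lo"], curve["or_hi"], alpha=0.3)
            ax.axhline(1.0, ls="--", lw=0.8)
            ax.set_xlabel("gestational week")
            ax.set_ylabel("OR per +5 g/L vs 110 g/L")
        else:
            traj = pd.DataFrame(r["trajectories"])
            for g, sub in traj.groupby("group"):
                ax.plot(sub["ga_weeks"], sub["hb_pred"], label=f"{name}={g}")
                ax.fill_between(sub["ga_weeks"], sub["lo"], sub["hi"], alpha=0.25)
            ax.set_xlabel("gestational weeks")
            ax.set_ylabel("predicted Hb (g/L)")
            ax.legend(fontsize=7)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(Path(out_dir) / f"{method}.png", dpi=120)
    plt.close(fig)


def cmd_report(results_dir, out_path=None) -> pd.DataFrame:
    """Collect every per-method OR table into one tidy summary CSV."""
    results_dir = Path(results_dir)
    rows = []
    for jf in sorted(results_dir.glob("*.json")):
        if jf.name in ("run_summary.json", "manifest.json"):
            continue
        with open(jf, encoding="utf-8") as fh:
            payload = json.load(fh)
        method = jf.stem
        for outcome, r in payload.get("per_outcome", {}).items():
            if "error" in r:
                rows.append({"method": method, "outcome": outcome,
                             "term": None, "or": None, "note": r["error"]})
                continue
            for rec in r.get("or_table", []):
                rows.append({"method": method, "outcome": outcome,
                             "term": rec["term"], "scale": rec.get("scale"),
                             "or": rec["or"], "or_lo": rec["or_lo"],
                             "or_hi": rec["or_hi"], "note": ""})
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
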