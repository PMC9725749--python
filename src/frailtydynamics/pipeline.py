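"""End-to-end pipeline: simulate -> preprocess -> counts -> fit -> derive ->
state-survival -> report, driven by a single YAML config.

Every stage reads/writes plain CSV in the output directory and is
independently re-runnable from those files; a manifest records the config
hash, package versions and the master seed, so reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .derived import build_rate_curve, curvature_terms, hazard_ratio_per_sd, posterior_spearman
from .diagnostics import posterior_predictive_check
from .panel import DeficitPanel
from .preprocess import filter_visits, prune_isolated_transitions
from .simulate import GroundTruth, simulate_cohort
from .statesurv import StateSurvivalModel, extract_state_intervals, generalized_logrank
from .transitions import binned_rates, count_transitions
from .mouse import MouseJointModel

__all__ = ["run_pipeline", "KNOWN_STAGES"]

KNOWN_STAGES = [
    "simulate", "preprocess", "counts", "fit_mouse", "derive",
    "state_survival", "report",
]

log = logging.getLogger("frailtydynamics.pipeline")


class PipelineError(RuntimeError):
    pass


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config, outdir) -> Path:
    """Execute the configured stages; returns the artifact directory.

    ``config``: dict or path to a YAML file. Unknown stage names fail
    validation before any computation.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    stages = config.get("stages", KNOWN_STAGES)
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise PipelineError(f"unknown stage names: {unknown}")
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    for stage in KNOWN_STAGES:
        if stage not in stages:
            continue
        log.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, seed, outdir, state)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config_hash": _hash_config(config),
        "seed": seed,
        "stages": [s for s in KNOWN_STAGES if s in stages],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _stage_simulate(cfg, seed, outdir, state):
    opts = cfg.get("simulate", {})
    truth_cfg = opts.get("truth")
    truth = GroundTruth.from_yaml(truth_cfg) if truth_cfg else GroundTruth()
    cohort = simulate_cohort(truth, int(opts.get("n_subjects", 60)), seed=seed)
    cohort.panel.write_csv(outdir / "panel")
    truth.to_yaml(outdir / "ground_truth.yaml")
    state["panel"] = cohort.panel


def _load_panel(cfg, outdir, state) -> DeficitPanel:
    if "panel" in state:
        return state["panel"]
    src = cfg.get("panel_dir", outdir / "panel")
    return DeficitPanel.read_csv(src)


def _stage_preprocess(cfg, seed, outdir, state):
    opts = cfg.get("preprocess", {})
    panel = _load_panel(cfg, outdir, state)
    panel = filter_visits(
        panel, min_gap=opts.get("min_gap"), max_gap=opts.get("max_gap"),
        min_visits=int(opts.get("min_visits", 2)),
    )
    if opts.get("prune_isolated", False):
        panel = prune_isolated_transitions(panel)
    panel.write_csv(outdir / "panel_clean")
    state["panel"] = panel


def _stage_counts(cfg, seed, outdir, state):
    panel = _load_panel(cfg, outdir, state)
    counts = count_transitions(panel)
    counts.write_csv(outdir / "transition_counts.csv")
    opts = cfg.get("counts", {})
    edges = opts.get("bin_edges")
    if edges is None:
        t = counts.data["time"]
        edges = np.linspace(float(t.min()), float(t.max() + counts.data["dt"].max()), 7)
    binned = binned_rates(counts, np.asarray(edges, float), age_column="time")
    binned.to_csv(outdir / "binned_rates.csv", index=False)
    state["counts"] = counts


def _stage_fit_mouse(cfg, seed, outdir, state):
    opts = cfg.get("fit_mouse", {})
    counts = state.get("counts")
    panel = _load_panel(cfg, outdir, state)
    if counts is None:
        counts = count_transitions(panel)
    model = MouseJointModel(counts, panel.survival)
    results = model.fit(
        n_warmup=int(opts.get("n_warmup", 300)),
        n_samples=int(opts.get("n_samples", 300)),
        n_chains=int(opts.get("n_chains", 2)),
        seed=seed + 1,
        on_bad_convergence=opts.get("on_bad_convergence", "warn"),
    )
    results.summary().to_csv(outdir / "mouse_posterior_summary.csv", index=False)
    results.posterior.to_tidy(
        ["beta_r", "beta_d", "gamma", "gamma_r", "gamma_d", "sigma"]
    ).to_csv(outdir / "mouse_posterior_draws.csv", index=False)
    state["mouse_results"] = results


def _stage_derive(cfg, seed, outdir, state):
    results = state.get("mouse_results")
    if results is None:
        raise PipelineError("derive requires fit_mouse in the same run")
    counts = state["counts"]
    d = counts.data
    t_grid = np.linspace(float(d["time"].min()), float(d["time"].max()), 40)
    profile = {
        "sex": 0.0, "treatment": 0.0,
        "a0": float(d["baseline_age"].median()),
    }
    curve = build_rate_curve(results, profile, t_grid)
    cd = curvature_terms(curve)
    rows = pd.DataFrame({
        "time": t_grid,
        "lambda_r_median": np.median(curve.lambda_r, axis=0),
        "lambda_d_median": np.median(curve.lambda_d, axis=0),
        "fi_median": np.median(curve.f, axis=0),
        "damage_term_median": np.median(cd.damage_term, axis=0),
        "repair_term_median": np.median(cd.repair_term, axis=0),
        "curvature_median": np.median(cd.total, axis=0),
        "prob_repair_dominates": cd.sign_probability(),
    })
    rows.to_csv(outdir / "derived_curves.csv", index=False)
    ages = d["time"].to_numpy(float) + d["baseline_age"].to_numpy(float)
    fi_row = (d["n"] / counts.n_items).to_numpy(float)
    lam_r = results.rate_draws(
        d["time"].to_numpy(float), d["sex"].to_numpy(float),
        d["treatment"].to_numpy(float), fi_row,
        d["baseline_age"].to_numpy(float), process="repair",
    )
    lam_d = results.rate_draws(
        d["time"].to_numpy(float), d["sex"].to_numpy(float),
        d["treatment"].to_numpy(float), fi_row,
        d["baseline_age"].to_numpy(float), process="damage",
    )
    sp_r = posterior_spearman(lam_r, ages)
    sp_d = posterior_spearman(lam_d, ages)
    hr = hazard_ratio_per_sd(results)
    summary = pd.DataFrame([
        {"quantity": "spearman_repair_age", "median": sp_r["median"],
         "q2.5": sp_r["q2.5"], "q97.5": sp_r["q97.5"]},
        {"quantity": "spearman_damage_age", "median": sp_d["median"],
         "q2.5": sp_d["q2.5"], "q97.5": sp_d["q97.5"]},
        {"quantity": "log_hr_repair_per_sd",
         "median": float(hr["log_hr_repair"].median()),
         "q2.5": float(hr["log_hr_repair"].quantile(0.025)),
         "q97.5": float(hr["log_hr_repair"].quantile(0.975))},
        {"quantity": "log_hr_damage_per_sd",
         "median": float(hr["log_hr_damage"].median()),
         "q2.5": float(hr["log_hr_damage"].quantile(0.025)),
         "q97.5": float(hr["log_hr_damage"].quantile(0.975))},
    ])
    summary.to_csv(outdir / "derived_summary.csv", index=False)


def _stage_state_survival(cfg, seed, outdir, state):
    opts = cfg.get("state_survival", {})
    panel = _load_panel(cfg, outdir, state)
    records = extract_state_intervals(panel)
    records.to_csv(outdir / "state_records.csv", index=False)
    bands = []
    for st in ("damaged", "undamaged"):
        sub = records[records["state"] == st]
        if (sub["censored"] == 0).sum() < 5:
            continue
        model = StateSurvivalModel(sub)
        res = model.fit(
            n_warmup=int(opts.get("n_warmup", 400)),
            n_samples=int(opts.get("n_samples", 400)),
            seed=seed + 2, on_bad_convergence="warn",
        )
        horizon = float(np.nanmax(sub[["t_upper", "t_censor"]].to_numpy()))
        grid = np.linspace(0.0, horizon, 30)
        band = res.survival_band(grid)
        band["state"] = st
        bands.append(band)
    if bands:
        pd.concat(bands, ignore_index=True).to_csv(
            outdir / "state_survival_curves.csv", index=False
        )
    group_col = opts.get("group", "treatment")
    tests = []
    for st in ("damaged", "undamaged"):
        sub = records[records["state"] == st]
        if sub[group_col].nunique() == 2 and (sub["censored"] == 0).sum() >= 10:
            stat, p = generalized_logrank(
                sub, sub[group_col].to_numpy(), int(opts.get("n_permutations", 499)),
                seed=seed + 3,
            )
            tests.append({"state": st, "group": group_col, "statistic": stat, "p_value": p})
    pd.DataFrame(tests).to_csv(outdir / "state_logrank_tests.csv", index=False)


def _stage_report(cfg, seed, outdir, state):
    results = state.get("mouse_results")
    lines = {}
    if results is not None:
        ppc = posterior_predictive_check(results, seed=seed + 4)
        ppc.summary().to_csv(outdir / "ppc_summary.csv", index=False)
        lines["overfit_flag"] = bool(ppc.overfit_flag)
    panel = _load_panel(cfg, outdir, state)
    counts = state.get("counts")
    if counts is not None:
        per_item = (
            panel.observations.groupby("deficit_id")["value"]
            .mean().rename("fraction_damaged").reset_index()
        )
        per_item.to_csv(outdir / "per_deficit_report.csv", index=False)
        lines["n_subjects"] = int(len(panel.subjects))
        lines["n_intervals"] = int(len(counts.data))
    (outdir / "report.json").write_text(json.dumps(lines, indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "counts": _stage_counts,
    "fit_mouse": _stage_fit_mouse,
    "derive": _stage_derive,
    "state_survival": _stage_state_survival,
    "report": _stage_report,
}
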