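"""End-to-end orchestration: generate -> metrics -> fit -> compare ->
analyze -> report, with a run manifest for reproducibility.

Every stage draws its randomness from the manifest seed, writes plain-text
outputs into the run directory, and logs one line per event.  Re-running
with the same config and seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import compare_models, fit_algorithm
from .metrics import (
    LapExcluded,
    choice_repeat_counts,
    classify_vte,
    fit_vte_threshold,
    logidphi,
    path_stereotypy,
)
from .stats import (
    fit_lmm,
    spec_transition,
    spec_vte_correlation,
    stay_probability_table,
)
from .synth import (
    DEFAULT_ZONES,
    PRESETS,
    CohortConfig,
    add_derived_covariates,
    frame_to_sessions,
    gen_cohort,
    gen_trajectory,
)
from .io import write_json, write_laps_tsv
from .task import TaskConfig

__all__ = ["run_pipeline", "make_manifest", "DEFAULT_CONFIG"]

log = logging.getLogger("twostep")

DEFAULT_CONFIG = {
    "seed": 0,
    "task": {},
    "cohort": {"n_rats": 3, "sessions_per_rat": 4, "laps_per_session": 74},
    "generate": {"preset": "hybrid"},
    "metrics": {"vte_rate": 0.3, "noise_sd": 0.3},
    "fit": {"algorithms": ["mf", "mb", "hybrid"], "chains": 2, "iters": 500, "warmup": 250},
    "analyze": {"bin_width": 2.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def make_manifest(config: dict, seed: int, out_dir: Path) -> dict:
    blob = json.dumps(config, sort_keys=True).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "version": __version__,
        "out_dir": str(out_dir),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [],
    }


class PipelineError(RuntimeError):
    def __init__(self, stage: str, manifest_path, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({cause}); manifest: {manifest_path}")
        self.stage = stage


def run_pipeline(config: dict | None = None, out_dir="twostep_run", seed=None) -> dict:
    """Run the configured stages at demo scale; returns the report dict.

    The report bundles the model-comparison table, stay-probability table,
    lap-wise VTE curve and mixed-model summaries computed on the generated
    data; all files land in ``out_dir`` next to ``manifest.json``.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = cfg["seed"] if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = make_manifest(cfg, seed, out)
    manifest_path = out / "manifest.json"
    write_json(manifest, manifest_path)
    report: dict = {"seed": seed, "config_hash": manifest["config_hash"]}
    rng = np.random.default_rng(seed)

    stage = "generate"
    try:
        task_cfg = TaskConfig(**cfg["task"]) if cfg["task"] else TaskConfig(
            n_laps=cfg["cohort"].get("laps_per_session", 74)
        )
        cohort_cfg = CohortConfig(**cfg["cohort"], seed=seed)
        preset = cfg["generate"]["preset"]
        algorithm = "mf" if preset == "random" else preset
        laps, truth = gen_cohort(
            cohort_cfg, algorithm, PRESETS[preset], task_cfg=task_cfg, seed=seed
        )
        write_laps_tsv(laps, out / "laps.tsv")
        truth.to_json(out / "ground_truth.json")
        manifest["outputs"] += ["laps.tsv", "ground_truth.json"]
        log.info("generate: %d laps (%s preset)", len(laps), preset)

        stage = "metrics"
        mcfg = cfg["metrics"]
        metrics = _metrics_stage(laps, mcfg, rng)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        manifest["outputs"].append("metrics.tsv")
        log.info("metrics: %d laps measured", len(metrics))

        stage = "fit"
        fcfg = cfg["fit"]
        sessions = frame_to_sessions(laps)
        fits = []
        for algo in fcfg["algorithms"]:
            res, _ = fit_algorithm(
                algo, sessions, task_cfg,
                n_chains=fcfg["chains"], n_iter=fcfg["iters"],
                n_warmup=fcfg["warmup"], seed=seed, compute_map=False,
            )
            fits.append(res)
            log.info("fit %s: DIC %.1f", algo, res.dic)
        write_json({f.algorithm: f.to_dict() for f in fits}, out / "fits.json")
        manifest["outputs"].append("fits.json")

        stage = "compare"
        ranking = compare_models(fits)
        ranking.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        report["model_comparison"] = ranking.to_dict(orient="records")
        manifest["outputs"].append("model_comparison.tsv")

        stage = "analyze"
        stay = stay_probability_table(laps, bin_width=cfg["analyze"]["bin_width"])
        stay.to_csv(out / "stay_probability.tsv", sep="\t", index=False)
        lmm_summaries = {}
        for spec in (spec_vte_correlation(), spec_transition("logidphi_cp2")):
            try:
                fit = fit_lmm(spec, metrics)
                lmm_summaries[spec.name] = fit.to_dict()
            except Exception as exc:
                lmm_summaries[spec.name] = {"error": str(exc)}
        report["lmm"] = lmm_summaries
        report["stay_probability"] = stay.assign(
            delay_bin=stay["delay_bin"].astype(str)
        ).to_dict(orient="records")
        manifest["outputs"].append("stay_probability.tsv")

        stage = "report"
        write_json(report, out / "report.json")
        manifest["outputs"].append("report.json")
        write_json(manifest, manifest_path)
    except Exception as exc:
        raise PipelineError(stage, manifest_path, exc) from exc
    return report


def _metrics_stage(laps: pd.DataFrame, mcfg: dict, rng) -> pd.DataFrame:
    """Synthesize trajectories for every lap and measure VTE/stereotypy."""
    zones = DEFAULT_ZONES
    df = add_derived_covariates(laps)
    vte_rate = float(mcfg.get("vte_rate", 0.3))
    noise_sd = float(mcfg.get("noise_sd", 0.3))
    rows = []
    from .synth import frame_to_sessions as _fts  # session grouping

    for (rat, sess), g in df.groupby(["rat_id", "session_id"], sort=False):
        paths: dict = {}
        lap_rows = []
        records = _fts(g)[0]
        repeats = choice_repeat_counts(records)
        for (_, row), rec, rep in zip(g.iterrows(), records, repeats):
            v1 = bool(rng.random() < vte_rate)
            v2 = bool(rng.random() < vte_rate)
            traj = gen_trajectory(
                rec, vte_cp1=v1, vte_cp2=v2, noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            entry = {
                "rat_id": rat, "session_id": sess, "lap": row["lap"],
                "transition": row["transition"], "rare": row["rare"],
                "rare_prev": row["rare_prev"], "delay_prev": row["delay_prev"],
                "delay_s": row["delay_s"], "repeat": row["repeat"],
                "n_repeats": rep, "vte_true_cp1": v1, "vte_true_cp2": v2,
            }
            for label, key in (("choice1", "logidphi_cp1"), ("choice2", "logidphi_cp2")):
                try:
                    entry[key] = logidphi(traj, zones[label])
                    entry[f"excluded_{label}"] = ""
                except LapExcluded as exc:
                    entry[key] = np.nan
                    entry[f"excluded_{label}"] = exc.reason
            ptype = (rec.choice1, rec.choice2)
            paths.setdefault(ptype, []).append((len(lap_rows), traj.body))
            lap_rows.append(entry)
        # stereotypy needs the full session's same-type paths
        for ptype, items in paths.items():
            for idx, body in items:
                others = [b for j, b in items if j != idx]
                try:
                    lap_rows[idx]["stereotypy"] = path_stereotypy(body, others)
                    lap_rows[idx]["excluded_stereotypy"] = ""
                except LapExcluded as exc:
                    lap_rows[idx]["stereotypy"] = np.nan
                    lap_rows[idx]["excluded_stereotypy"] = exc.reason
        rows.extend(lap_rows)
    metrics = pd.DataFrame(rows)
    pooled = metrics["logidphi_cp1"].dropna()
    if len(pooled) >= 100:
        thr = fit_vte_threshold(pooled.to_numpy())
        metrics["vte_cp1"] = [
            classify_vte(v, thr) if np.isfinite(v) else False
            for v in metrics["logidphi_cp1"]
        ]
        metrics.attrs["vte_threshold_cp1"] = thr
    return metrics
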