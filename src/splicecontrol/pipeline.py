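"""End-to-end orchestration: simulate/load -> pseudotime -> trends -> infer -> control.

A run is configured by a flat mapping (YAML or JSON on disk); unknown keys
are rejected.  One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` so every stage is
independently reproducible from its persisted inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control as ctl
from . import netinfer, trends
from . import pseudotime as pt
from .io import OmicsPanel, read_panel, write_panel
from .simulate import SimConfig, simulate_panel

log = logging.getLogger("splicecontrol")

STAGES = ("simulate", "pseudotime", "trends", "infer", "control")

DEFAULT_CONFIG: dict = {
    "panel_dir": None,          # load a panel from here unless simulate=True
    "simulate": True,
    "n_as": 5, "n_rbp": 3, "n_tf": 2, "n_samples": 100,
    "density": 0.4, "noise_mean": 0.0, "noise_cv": 0.0,
    "k_neighbors": 10,
    "top_as": None, "top_rbp": None, "top_tf": None,   # None = keep all
    "bandwidth": 0.05,
    "iters": 4000, "burn": 1000, "ci_level": 0.9,
    "control_targets": None,    # None = all AS nodes of the inferred network
    "control_inputs": None,     # None = all TF nodes
    "control_mode": "enumerate",
    "walk_steps": 10_000, "walk_burn": 1000, "walk_thin": 10,
    "seed": 0,
    "out_dir": "run",
}


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw or {})


def validate_config(overrides: dict) -> dict:
    unknown = set(overrides) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **overrides}
    if not cfg["simulate"] and not cfg["panel_dir"]:
        raise ValueError("either simulate=true or panel_dir must be given")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: dict) -> dict:
    """Execute all stages, writing artifacts to ``out_dir``; returns the report."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"config": dict(cfg), "stages": {}}
    truth = None
    try:
        t0 = time.time()
        if cfg["simulate"]:
            sim_cfg = SimConfig(
                n_as=cfg["n_as"], n_rbp=cfg["n_rbp"], n_tf=cfg["n_tf"],
                n_samples=cfg["n_samples"], density=cfg["density"],
                noise_mean=cfg["noise_mean"], noise_cv=cfg["noise_cv"],
                seed=stage_seed(cfg["seed"], "simulate"),
            )
            panel, truth = simulate_panel(sim_cfg)
            write_panel(panel, out / "panel")
            truth.to_json(out / "panel" / "truth.json")
            report["stages"]["simulate"] = {
                "seed": sim_cfg.seed, "n_samples": sim_cfg.n_samples,
                "true_edges": int(len(truth.edges())),
                "seconds": round(time.time() - t0, 3),
            }
        else:
            panel = read_panel(cfg["panel_dir"])
            report["stages"]["simulate"] = {"loaded_from": str(cfg["panel_dir"])}

        t0 = time.time()
        try:
            assignment = pt.infer_pseudotime(panel, k=min(cfg["k_neighbors"], panel.n_samples - 1))
        except Exception as exc:
            raise StageFailure("pseudotime", exc) from exc
        assignment.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        report["stages"]["pseudotime"] = {
            "k": cfg["k_neighbors"], "seconds": round(time.time() - t0, 3),
        }

        t0 = time.time()
        try:
            table = trends.trend_table(panel, assignment.scores)
            k_as = cfg["top_as"] or panel.as_matrix.shape[0]
            k_rbp = cfg["top_rbp"] or panel.rbp_matrix.shape[0]
            k_tf = cfg["top_tf"] or panel.tf_matrix.shape[0]
            selection = trends.select_top(table, k_as=k_as, k_rbp=k_rbp, k_tf=k_tf)
            panel_sel = trends.subset_panel(panel, selection)
        except Exception as exc:
            raise StageFailure("trends", exc) from exc
        table.to_csv(out / "trends.tsv", sep="\t", index=False)
        report["stages"]["trends"] = {
            "selected": {lay: len(v) for lay, v in selection.items()},
            "seconds": round(time.time() - t0, 3),
        }

        t0 = time.time()
        try:
            network = netinfer.infer_network(
                panel_sel, assignment.rank_uniform(), bandwidth=cfg["bandwidth"],
                iters=cfg["iters"], burn=cfg["burn"], ci_level=cfg["ci_level"],
                seed=stage_seed(cfg["seed"], "infer"),
            )
        except Exception as exc:
            raise StageFailure("infer", exc) from exc
        network.write_edges(out / "edges.tsv")
        report["stages"]["infer"] = {
            "candidate_edges": int(len(network.edges)),
            "called_edges": int(network.edges["called"].sum()),
            "seconds": round(time.time() - t0, 3),
        }

        t0 = time.time()
        try:
            targets = cfg["control_targets"] or selection["AS"]
            inputs = cfg["control_inputs"] or selection["TF"]
            problem = ctl.ControlProblem.from_network(network, targets=targets, inputs=inputs)
            solution = ctl.solve_control(
                problem, mode=cfg["control_mode"], steps=cfg["walk_steps"],
                burn=cfg["walk_burn"], thin=cfg["walk_thin"],
                seed=stage_seed(cfg["seed"], "control"),
            )
        except Exception as exc:
            raise StageFailure("control", exc) from exc
        control_report = {
            "drivers": solution.drivers,
            "rank": solution.rank,
            "n_targets": solution.n_targets,
            "minimal_certified": solution.minimal_certified,
            "infeasible_targets": solution.infeasible_targets,
            "frequencies": None if solution.frequencies is None
            else {k: float(v) for k, v in solution.frequencies.items()},
            "key_tfs": solution.key_tfs,
            "paths": solution.paths,
        }
        (out / "control.json").write_text(json.dumps(control_report, indent=1))
        report["stages"]["control"] = {
            "n_drivers": len(solution.drivers), "key_tfs": solution.key_tfs,
            "seconds": round(time.time() - t0, 3),
        }

        if truth is not None:
            from .metrics import confusion_metrics, rmse, roc_auc, spearman_rho

            true_s = truth.pseudotime.reindex(panel.sample_ids).to_numpy()
            inferred = assignment.scores.reindex(panel.sample_ids).to_numpy()
            key = pd.MultiIndex.from_tuples(
                list(zip(network.edges["source"], network.edges["target"]))
            )
            y_true = truth.edge_indicator().reindex(key).to_numpy()
            cm = confusion_metrics(network.edges["called"].to_numpy(), y_true)
            report["benchmark"] = {
                "rho": spearman_rho(inferred, true_s),
                "rmse": rmse(inferred, true_s),
                "auc": roc_auc(network.edges["score"].to_numpy(), y_true),
                **cm,
            }
    except StageFailure as fail:
        report["failed_stage"] = fail.stage
        report["error"] = str(fail.cause)
        _write_report(report, out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    tmp = out / "report.json.tmp"
    tmp.write_text(json.dumps(report, indent=1, default=str))
    tmp.replace(out / "report.json")


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name for the report."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
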