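"""Stage orchestration behind the command-line interface.

A single YAML config drives the whole run: simulate (or load real TSVs),
preprocess, smooth, cluster, characterize, influence, robustness.  Every
stage writes its tables under the output directory, a MANIFEST records the
config hash, seed, resolved defaults and any failure point, and a rerun
with the same config and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, preprocess, simulate
from .clustering import build_knn_laplacian, consensus_cluster, stratify_range
from .influence import influence_analysis
from .robustness import robustness_check
from .smoothing import smooth_profiles
from .subgroup_stats import enrichment_test, stage_association, survival_scan

log = logging.getLogger(__name__)

#: Resolved defaults for every tunable; all exposed as config keys.
DEFAULTS = {
    "seed": 0,
    "min_weight": 0.0,
    "keep_all": False,
    "alpha": 0.7,
    "tol": 1e-6,
    "max_iter": 100,
    "norm_mode": "row_stochastic",
    "quantile_norm": True,
    "lam": 1.0,
    "knn_k": 11,
    "n_runs": 100,
    "subsample_frac": 0.8,
    "nmf_iter": 1000,
    "nmf_tol": 1e-6,
    "k": None,
    "kmin": 3,
    "kmax": 15,
    "n_perm": 1000,
    "score_min": 15.0,
    "q_max": 0.05,
    "s0_mode": "auto",
    "robustness_frac": 0.8,
    "robustness_reps": 20,
}

STAGES = (
    "simulate", "preprocess", "smooth", "cluster",
    "enrich", "survival", "influence", "robustness",
)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _resolve(cfg: dict, stage: str, key: str, override=None):
    if override is not None:
        return override
    block = cfg.get(stage, {}) or {}
    if key in block:
        return block[key]
    if key in cfg:
        return cfg[key]
    return DEFAULTS[key]


def run_pipeline(
    config_path,
    outdir,
    seed: int | None = None,
    stages=None,
    k: int | None = None,
    kmin: int | None = None,
    kmax: int | None = None,
) -> Path:
    """Execute the enabled stages; returns the artifact directory.

    Any stage error leaves the already-written outputs in place and a
    MANIFEST noting the failure point before the exception propagates.
    """
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(_resolve(cfg, "global", "seed", seed))
    rng = np.random.default_rng(seed)

    enabled = [s for s in STAGES if s in cfg] if stages is None else list(stages)
    if stages is None and not enabled:
        enabled = list(STAGES)
    # a config that defines its cohort via simulation needs that stage first
    if "simulate" in cfg and "simulate" not in enabled and not cfg.get("inputs"):
        enabled = ["simulate"] + enabled

    config_text = Path(config_path).read_text()
    manifest = {
        "config_hash": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "stages": enabled,
        "resolved": {},
        "status": "running",
    }

    def _write_manifest():
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str))

    state: dict = {}
    try:
        for stage in enabled:
            log.info("stage: %s", stage)
            _run_stage(stage, cfg, outdir, seed, rng, state, manifest, k, kmin, kmax)
            manifest.setdefault("completed", []).append(stage)
            _write_manifest()
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        _write_manifest()
        raise
    _write_manifest()
    return outdir


def _load_inputs(cfg: dict, outdir: Path, state: dict) -> None:
    """Populate events/network/clinical/expression from config paths or sim output."""
    inputs = cfg.get("inputs", {}) or {}
    simdir = outdir / "cohort"

    def path_for(name):
        if name in inputs:
            return inputs[name]
        candidate = simdir / f"{name}.tsv"
        return candidate if candidate.exists() else None

    if "events" not in state:
        events_path = path_for("events")
        if events_path is None:
            raise FileNotFoundError("no events input: give inputs.events or run simulate")
        ann = inputs.get("event_annotation")
        if ann is None and (simdir / "event_annotation.tsv").exists():
            ann = simdir / "event_annotation.tsv"
        state["events"] = data_io.read_event_matrix(events_path, annotation_path=ann)
    if "network" not in state:
        net_path = path_for("network")
        if net_path is None:
            raise FileNotFoundError("no network input")
        state["network"] = data_io.read_network(
            net_path, min_weight=float(_resolve(cfg, "preprocess", "min_weight"))
        )
    if "clinical" not in state:
        clin_path = path_for("clinical")
        state["clinical"] = data_io.read_clinical(clin_path) if clin_path else None
    if "expression" not in state:
        expr_path = path_for("expression")
        state["expression"] = data_io.read_matrix(expr_path) if expr_path else None


def _run_stage(stage, cfg, outdir, seed, rng, state, manifest, k, kmin, kmax):
    if stage == "simulate":
        sim_block = dict(cfg.get("simulate", {}) or {})
        sim_block.setdefault("seed", seed)
        sim_cfg = simulate.SimConfig(**sim_block)
        cohort = simulate.generate_cohort(sim_cfg)
        simulate.write_cohort(cohort, outdir / "cohort")
        state["cohort"] = cohort
        manifest["resolved"]["simulate"] = asdict(sim_cfg)
        return

    if stage == "preprocess":
        _load_inputs(cfg, outdir, state)
        genes = preprocess.expand_events(state["events"])
        keep_all = bool(_resolve(cfg, "preprocess", "keep_all"))
        aligned, net, report = preprocess.align_to_network(
            genes, state["network"], keep_all=keep_all
        )
        state["gene_matrix"], state["aligned_net"] = aligned, net
        data_io.write_matrix(aligned, outdir / "gene_matrix.tsv", index_name="sample_id")
        report.to_csv(outdir / "coverage_report.tsv", sep="\t")
        manifest["resolved"]["preprocess"] = {"keep_all": keep_all}
        return

    if stage == "smooth":
        params = {key: _resolve(cfg, "smooth", key)
                  for key in ("alpha", "tol", "max_iter", "norm_mode", "quantile_norm")}
        profile = smooth_profiles(
            state["gene_matrix"], state["aligned_net"],
            alpha=float(params["alpha"]), tol=float(params["tol"]),
            max_iter=int(params["max_iter"]), norm_mode=params["norm_mode"],
            quantile_norm=bool(params["quantile_norm"]),
        )
        state["profile"] = profile
        data_io.write_matrix(profile.values, outdir / "smoothed.tsv", index_name="sample_id")
        manifest["resolved"]["smooth"] = params
        return

    if stage == "cluster":
        params = {key: _resolve(cfg, "cluster", key)
                  for key in ("lam", "knn_k", "n_runs", "subsample_frac",
                              "nmf_iter", "nmf_tol", "alpha", "k", "kmin", "kmax")}
        if k is not None:
            params["k"] = k
        if kmin is not None:
            params["kmin"] = kmin
        if kmax is not None:
            params["kmax"] = kmax
        profile = state["profile"]
        L, _ = build_knn_laplacian(
            state["aligned_net"], list(profile.values.columns),
            alpha=float(params["alpha"]), knn_k=int(params["knn_k"]),
        )
        state["laplacian"] = L
        common = dict(
            L=L, lam=float(params["lam"]), n_runs=int(params["n_runs"]),
            subsample_frac=float(params["subsample_frac"]),
            n_iter=int(params["nmf_iter"]), tol=float(params["nmf_tol"]),
        )
        if params["k"] is not None:
            result = consensus_cluster(profile, int(params["k"]), seed=seed, **common)
            results = {int(params["k"]): result}
            landscape = result.assignment.to_frame(name=f"k={params['k']}")
        else:
            k_values = range(int(params["kmin"]), int(params["kmax"]) + 1)
            results, landscape = stratify_range(profile, k_values, seed=seed, **common)
        state["clusterings"] = results
        state["assignment"] = results[max(results)].assignment
        landscape.to_csv(outdir / "landscape.tsv", sep="\t")
        for kk, res in results.items():
            data_io.write_matrix(res.consensus, outdir / f"consensus_k{kk}.tsv",
                                 index_name="sample_id")
            res.assignment.to_frame().to_csv(outdir / f"assignment_k{kk}.tsv", sep="\t")
        manifest["resolved"]["cluster"] = params
        return

    if stage == "enrich":
        clinical = state.get("clinical")
        if clinical is None:
            raise ValueError("enrich stage needs a clinical table")
        table = enrichment_test(state["assignment"], clinical["cancer_type"])
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        state["enrichment"] = table
        return

    if stage == "survival":
        clinical = state.get("clinical")
        if clinical is None:
            raise ValueError("survival stage needs a clinical table")
        scan = survival_scan(clinical, state["assignment"])
        scan.to_csv(outdir / "survival_scan.tsv", sep="\t", index=False)
        rows = []
        for subgroup in sorted(state["assignment"].unique()):
            for cancer_type in sorted(clinical["cancer_type"].dropna().unique()):
                for feature in ("stage", "grade"):
                    try:
                        _, p, se = stage_association(
                            clinical, state["assignment"], subgroup, cancer_type,
                            feature=feature, seed=seed,
                        )
                    except ValueError:
                        continue
                    rows.append({"subgroup": subgroup, "cancer_type": cancer_type,
                                 "feature": feature, "fisher_p": p, "mc_se": se})
        pd.DataFrame(rows).to_csv(outdir / "stage_grade.tsv", sep="\t", index=False)
        return

    if stage == "influence":
        params = {key: _resolve(cfg, "influence", key)
                  for key in ("n_perm", "score_min", "q_max", "s0_mode")}
        results = influence_analysis(
            state["profile"], state["assignment"], state["aligned_net"],
            expression=state.get("expression"),
            n_perm=int(params["n_perm"]), seed=seed,
            score_min=float(params["score_min"]), q_max=float(params["q_max"]),
            s0_mode=params["s0_mode"],
        )
        infdir = outdir / "influence"
        infdir.mkdir(exist_ok=True)
        for subgroup, sam in results["sam"].items():
            sam.to_csv(infdir / f"sam_subgroup_{subgroup}.tsv", sep="\t")
        for subgroup, genes in results["gene_sets"].items():
            (infdir / f"genes_subgroup_{subgroup}.txt").write_text(
                "\n".join(genes) + ("\n" if genes else "")
            )
        for subgroup, modules in results["modules"].items():
            for module in modules:
                data_io.write_subnetwork(
                    module.graph,
                    infdir / f"module_subgroup_{subgroup}_c{module.component_id}.graphml",
                )
        for subgroup, wtab in results["expression"].items():
            wtab.to_csv(infdir / f"expression_subgroup_{subgroup}.tsv", sep="\t")
        results["overlap"].to_csv(infdir / "overlap.tsv", sep="\t")
        state["influence"] = results
        manifest["resolved"]["influence"] = params
        return

    if stage == "robustness":
        params = {
            "frac": float(_resolve(cfg, "robustness", "robustness_frac")),
            "reps": int(_resolve(cfg, "robustness", "robustness_reps")),
            "n_runs": int(_resolve(cfg, "robustness", "n_runs")),
            "subsample_frac": float(_resolve(cfg, "robustness", "subsample_frac")),
            "lam": float(_resolve(cfg, "robustness", "lam")),
            "nmf_iter": int(_resolve(cfg, "robustness", "nmf_iter")),
            "nmf_tol": float(_resolve(cfg, "robustness", "nmf_tol")),
        }
        assignment = state["assignment"]
        report = robustness_check(
            state["profile"], assignment, k=int(assignment.nunique()),
            frac=params["frac"], reps=params["reps"], seed=seed,
            L=state.get("laplacian"), lam=params["lam"], n_runs=params["n_runs"],
            subsample_frac=params["subsample_frac"],
            n_iter=params["nmf_iter"], tol=params["nmf_tol"],
        )
        report.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
        manifest["resolved"]["robustness"] = params
        return

    raise ValueError(f"unknown stage {stage!r}")
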