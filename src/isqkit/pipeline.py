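"""End-to-end pipeline: simulate/load -> descriptives -> CFA -> item
reduction -> GRM -> category collapse -> GRM refit -> DIF -> scoring.

Each enabled stage writes its artifact files into the output directory and
records an entry in a machine-readable run manifest; a failing stage halts
the run with the stage name while preserving artifacts already written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfa import OrdinalFactorModel, omega_categorical
from .data import ResponseMatrix
from .dif import iterative_wald_dif, make_groups, regress_scores
from .grm import GradedResponseModel
from .isq import ISQ_GENERALITY
from .polychoric import (bootstrap_polychoric, item_descriptives,
                         polychoric_matrix, redundancy_screen)
from .reduction import (CollapseMap, ReductionConfig, apply_collapse,
                        derive_collapse_map, reduce_items)
from .scoring import score_responses
from .simulate import simulate_responses, study_like_config, write_simulation

log = logging.getLogger("isqkit.pipeline")

_ALL_STAGES = ("descriptives", "cfa", "reduction", "irt", "collapse",
               "dif", "scoring")


class PipelineError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


@dataclass
class PipelineConfig:
    output_dir: str = "pipeline_out"
    seed: int = 0
    responses: Optional[str] = None      # CSV path; None -> simulate
    covariates: Optional[str] = None
    stages: List[str] = field(default_factory=lambda: list(_ALL_STAGES))
    corr_cutoff: float = 0.7
    epc_cutoff: float = 0.1
    generality: Dict[str, float] = field(default_factory=lambda: dict(ISQ_GENERALITY))
    batch_mode: bool = False
    n_quad: int = 61
    n_boot_gamma: int = 200
    n_boot_omega: int = 200
    n_boot_marginal: int = 1000
    dif_variables: List[dict] = field(default_factory=lambda: [
        {"variable": "cohort"},
        {"variable": "sex"},
        {"variable": "age", "cutpoint": 40},
        {"variable": "income", "cutpoint": 50_000},
    ])
    calibration: Optional[str] = None    # score-only runs
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def reduction_config(self) -> ReductionConfig:
        return ReductionConfig(corr_cutoff=self.corr_cutoff,
                               epc_cutoff=self.epc_cutoff,
                               generality=self.generality,
                               batch_mode=self.batch_mode,
                               n_boot=self.n_boot_gamma, seed=self.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the artifact bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": {}, "inputs": {"responses": config.responses,
                                         "covariates": config.covariates}}
    artifacts: dict = {}

    def record(stage, t0, files):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "files": files}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    def run_stage(stage, fn):
        if stage not in config.stages and stage != "load":
            log.info("stage %s disabled", stage)
            return
        t0 = time.time()
        log.info("stage %s ...", stage)
        try:
            files = fn() or []
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise PipelineError(stage, exc) from exc
        record(stage, t0, files)

    # ---- load / simulate -------------------------------------------------
    def stage_load():
        if config.responses is not None:
            artifacts["X"] = ResponseMatrix.from_csv(config.responses,
                                                     config.covariates)
            return []
        sim = study_like_config(seed=config.seed)
        X, truth = simulate_responses(sim)
        artifacts["X"], artifacts["truth"] = X, truth
        write_simulation(X, truth, out / "simulated")
        return ["simulated/responses.csv", "simulated/covariates.csv",
                "simulated/ground_truth.json"]

    run_stage("load", stage_load)
    X = artifacts["X"]

    if config.calibration is not None and config.stages == ["scoring"]:
        # score-only run against a shipped calibration
        st = score_responses(config.calibration, X)
        st.to_csv(out / "scores.csv")
        artifacts["scores"] = st
        record("scoring", time.time(), ["scores.csv"])
        return artifacts

    # ---- descriptives ----------------------------------------------------
    def stage_descriptives():
        R = polychoric_matrix(X)
        artifacts["R"] = R
        desc = item_descriptives(X, R, cutoff=config.corr_cutoff)
        screen = redundancy_screen(R, config.corr_cutoff)
        artifacts["descriptives"], artifacts["screen"] = desc, screen
        desc.to_csv(out / "descriptives.csv")
        R.to_csv(out / "polychoric.csv")
        screen.pairs.to_csv(out / "redundancy_flags.csv", index=False)
        return ["descriptives.csv", "polychoric.csv", "redundancy_flags.csv"]

    run_stage("descriptives", stage_descriptives)

    # ---- CFA on the full form -------------------------------------------
    def stage_cfa():
        R = artifacts.get("R") or polychoric_matrix(X)
        boot = bootstrap_polychoric(X, n_boot=config.n_boot_gamma,
                                    seed=config.seed)
        artifacts["boot_reps"] = boot
        model = OrdinalFactorModel.from_data(X, R=R, boot_reps=boot)
        res = model.fit()
        artifacts["cfa_full"] = res
        res.loading_table().to_csv(out / "cfa_loadings.csv")
        fit = res.fit_indices()
        mi = res.modification_indices(epc_cutoff=config.epc_cutoff)
        mi.to_csv(out / "cfa_modification_indices.csv", index=False)
        rel = omega_categorical(res, X, n_boot=config.n_boot_omega,
                                seed=config.seed)
        artifacts["omega_full"] = rel
        summary = {"T": res.statistic, "df": res.df, "p": res.pvalue,
                   **fit.to_dict(), "omega": rel.omega,
                   "omega_ci": list(rel.ci)}
        with open(out / "cfa_fit.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return ["cfa_loadings.csv", "cfa_modification_indices.csv",
                "cfa_fit.json"]

    run_stage("cfa", stage_cfa)

    # ---- item reduction --------------------------------------------------
    def stage_reduction():
        R = artifacts.get("R") or polychoric_matrix(X)
        trace = reduce_items(X, R, config.reduction_config(),
                             boot_reps=artifacts.get("boot_reps"))
        artifacts["trace"] = trace
        trace.to_json(out / "reduction_trace.json")
        Xr = X.select_items(trace.retained)
        artifacts["X_reduced"] = Xr
        model = OrdinalFactorModel.from_data(
            Xr, R=R.submatrix(trace.retained),
            boot_reps=_subset_boot(artifacts.get("boot_reps"), R, trace.retained))
        res = model.fit()
        artifacts["cfa_reduced"] = res
        res.loading_table().to_csv(out / "cfa_reduced_loadings.csv")
        with open(out / "cfa_reduced_fit.json", "w") as fh:
            json.dump({"T": res.statistic, "df": res.df, "p": res.pvalue,
                       **res.fit_indices().to_dict()}, fh, indent=1)
        return ["reduction_trace.json", "cfa_reduced_loadings.csv",
                "cfa_reduced_fit.json"]

    run_stage("reduction", stage_reduction)
    Xr = artifacts.get("X_reduced", X)

    # ---- GRM on the reduced form ----------------------------------------
    def stage_irt():
        res = GradedResponseModel(Xr, n_quad=config.n_quad).fit()
        artifacts["grm7"] = res
        res.params_table().to_csv(out / "grm_params.csv")
        stats7 = res.c2(Xr)
        ld7 = res.ld_chi2(Xr)
        rel = res.marginal_reliability(Xr, n_boot=config.n_boot_marginal,
                                       seed=config.seed)
        artifacts["fit7"], artifacts["ld7"], artifacts["rho7"] = stats7, ld7, rel
        with open(out / "grm_fit.json", "w") as fh:
            json.dump({"C2": stats7.statistic, "df": stats7.df,
                       "p": stats7.pvalue, "RMSEA_C2": stats7.rmsea,
                       "CFI_C2": stats7.cfi, "SRMR": stats7.srmr,
                       "marginal_reliability": rel.rho,
                       "marginal_reliability_ci": list(rel.ci),
                       "max_LD": ld7.max_pair()[2]}, fh, indent=1)
        res.item_curves().to_csv(out / "grm_curves.csv", index=False)
        return ["grm_params.csv", "grm_fit.json", "grm_curves.csv"]

    run_stage("irt", stage_irt)

    # ---- category collapse + refit --------------------------------------
    def stage_collapse():
        grm7 = artifacts["grm7"]
        cmap = derive_collapse_map(grm7.item_params)
        artifacts["collapse_map"] = cmap
        cmap.to_json(out / "collapse_map.json")
        Xc = apply_collapse(Xr, cmap)
        artifacts["X_collapsed"] = Xc
        res = GradedResponseModel(Xc, n_quad=config.n_quad).fit()
        artifacts["grm5"] = res
        res.params_table().to_csv(out / "grm_collapsed_params.csv")
        stats5 = res.c2(Xc)
        rel5 = res.marginal_reliability(Xc, n_boot=config.n_boot_marginal,
                                        seed=config.seed)
        sc7 = grm7.eap_scores(Xr)
        sc5 = res.eap_scores(Xc)
        r = float(np.corrcoef(sc7.theta, sc5.theta)[0, 1])
        artifacts["collapse_score_r"] = r
        res.save_calibration(out / "calibration.json",
                             collapse_map={str(k): v
                                           for k, v in cmap.mapping.items()},
                             metadata={"n": Xc.n, "seed": config.seed})
        with open(out / "grm_collapsed_fit.json", "w") as fh:
            json.dump({"C2": stats5.statistic, "df": stats5.df,
                       "p": stats5.pvalue, "RMSEA_C2": stats5.rmsea,
                       "CFI_C2": stats5.cfi, "SRMR": stats5.srmr,
                       "marginal_reliability": rel5.rho,
                       "score_correlation_7pt_vs_5pt": r}, fh, indent=1)
        return ["collapse_map.json", "grm_collapsed_params.csv",
                "grm_collapsed_fit.json", "calibration.json"]

    run_stage("collapse", stage_collapse)
    Xfinal = artifacts.get("X_collapsed", Xr)

    # ---- DIF -------------------------------------------------------------
    def stage_dif():
        if Xfinal.covariates is None:
            raise ValueError("DIF requires covariates")
        reports = []
        for spec in config.dif_variables:
            var = spec["variable"]
            try:
                gs = make_groups(Xfinal.covariates, var,
                                 cutpoint=spec.get("cutpoint"),
                                 mapping=spec.get("mapping"))
            except ValueError as exc:
                log.warning("DIF grouping %s skipped: %s", var, exc)
                continue
            res = iterative_wald_dif(Xfinal, gs.labels.to_numpy(),
                                     n_quad=config.n_quad, group_spec=gs)
            tbl = res.table.copy()
            tbl.insert(0, "grouping", var)
            reports.append(tbl)
            artifacts[f"dif_{var}"] = res
        if reports:
            full = pd.concat(reports, ignore_index=True)
            full.to_csv(out / "dif_report.csv", index=False)
            artifacts["dif_report"] = full
        return ["dif_report.csv"] if reports else []

    run_stage("dif", stage_dif)

    # ---- scoring + demographic regression -------------------------------
    def stage_scoring():
        grm = artifacts.get("grm5") or artifacts.get("grm7") \
            or GradedResponseModel(Xfinal, n_quad=config.n_quad).fit()
        scores = grm.eap_scores(Xfinal)
        scores["scale_used"] = Xfinal.n_categories
        scores.to_csv(out / "scores.csv")
        artifacts["scores"] = scores
        files = ["scores.csv"]
        if Xfinal.covariates is not None and \
                {"age", "sex"} <= set(Xfinal.covariates.columns):
            reg = regress_scores(scores, Xfinal.covariates)
            artifacts["regression"] = reg
            with open(out / "regression.json", "w") as fh:
                json.dump({"coef": reg.params.to_dict(),
                           "p": reg.pvalues.to_dict(),
                           "r_squared": reg.rsquared,
                           "beta_F_minus_M": reg.beta_f_minus_m,
                           "n_used": reg.n_used}, fh, indent=1)
            files.append("regression.json")
        return files

    run_stage("scoring", stage_scoring)
    return artifacts


def _subset_boot(boot_reps, R, items):
    if boot_reps is None:
        return None
    pairs = R.pair_index()
    ids = R.item_ids
    keep = set(items)
    cols, order = [], []
    for m, (i, j) in enumerate(pairs):
        if ids[i] in keep and ids[j] in keep:
            order.append((items.index(ids[i]), items.index(ids[j]), m))
    # reorder to the submatrix's own (i<j) lexicographic pair order
    order.sort(key=lambda t: (min(t[0], t[1]), max(t[0], t[1])))
    cols = [m for _, _, m in order]
    return boot_reps[:, cols]
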