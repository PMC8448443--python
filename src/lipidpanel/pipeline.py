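"""End-to-end orchestration: QC -> network -> eigenlipids -> panel models ->
latent classes -> PVAR -> temporal network, driven by one YAML config.

Every stage reads the previous stage's in-memory outputs, writes plain CSV
or JSON artifacts into the output directory, and is fully deterministic
given the configured seed. A run manifest lists every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from . import lcmm as plcmm
from . import network as pnet
from . import panel as ppanel
from . import pvar as ppvar
from . import qc as pqc
from . import simulate as psim

log = logging.getLogger("lipidpanel")

STAGES = ("qc", "network", "panel", "lcmm", "pvar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str = "lipidpanel_out"
    seed: int = 0
    simulate: dict | None = None  # SimConfig kwargs; mutually exclusive w/ cohort_csv
    cohort_csv: str | None = None
    raw_dir: str | None = None  # directory with raw feature table CSVs
    simulate_raw: dict | None = None  # simulate_raw_features kwargs
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    qc: dict = field(default_factory=dict)  # thresholds
    network: dict = field(default_factory=dict)  # beta, min_size, cut_height
    panel: dict = field(default_factory=dict)  # alpha
    lcmm: dict = field(default_factory=dict)  # response, k_range, restarts...
    pvar: dict = field(default_factory=dict)  # lags, transform, system, alpha...
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        cfg.stages = stages
        if cfg.simulate is None and cfg.cohort_csv is None:
            raise ValueError("config needs either 'simulate' or 'cohort_csv'")
        if cfg.cohort_csv and not os.path.exists(cfg.cohort_csv):
            raise ValueError(f"cohort_csv does not exist: {cfg.cohort_csv}")
        if cfg.raw_dir and not os.path.isdir(cfg.raw_dir):
            raise ValueError(f"raw_dir does not exist: {cfg.raw_dir}")
        return cfg

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    started: float
    finished: float | None = None
    stage_info: dict = field(default_factory=dict)
    files: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def _write_csv(frame: pd.DataFrame, outdir, name, files, index=False) -> str:
    path = os.path.join(outdir, name)
    frame.to_csv(path, index=index)
    files.append(path)
    return path


def _write_json(obj, outdir, name, files) -> str:
    path = os.path.join(outdir, name)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
    files.append(path)
    return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.content_hash(),
        version=__version__,
        seed=config.seed,
        started=time.time(),
    )
    files = manifest.files
    current_stage = "input"
    try:
        # ---- input / simulation ----
        if config.simulate is not None:
            sim_cfg = psim.SimConfig(seed=config.seed, **config.simulate)
            panel, truth = psim.simulate_study(sim_cfg)
            pio.write_cohort_csv(panel, os.path.join(outdir, "cohort.csv"))
            files.append(os.path.join(outdir, "cohort.csv"))
            truth.to_json(os.path.join(outdir, "ground_truth.json"))
            files.append(os.path.join(outdir, "ground_truth.json"))
        else:
            panel = pio.read_cohort_csv(config.cohort_csv)
        manifest.stage_info["input"] = {
            "n_rows": len(panel),
            "n_children": int(panel["child_id"].nunique()),
        }

        raw = None
        if config.raw_dir:
            raw = pqc.read_raw_table(config.raw_dir)
        elif config.simulate_raw is not None:
            raw, _ = psim.simulate_raw_features(
                seed=config.seed, **config.simulate_raw
            )

        # ---- QC ----
        current_stage = "qc"
        if config.stages.get("qc") and raw is not None:
            filtered, report = pqc.apply_qc_filters(raw, config.qc.get("thresholds"))
            _write_csv(pqc.report_to_frame(report), outdir, "qc_report.csv", files, index=True)
            _write_json(
                {
                    "thresholds": report.thresholds,
                    "attrition": report.attrition,
                    "n_in": raw.n_features,
                    "n_out": filtered.n_features,
                    "not_evaluable": report.not_evaluable,
                },
                outdir,
                "qc_summary.json",
                files,
            )
            manifest.stage_info["qc"] = report.attrition

        # ---- network ----
        lipid_cols = pio.feature_columns(panel)
        me_cols = [c for c in panel.columns if c.startswith("me_")]
        current_stage = "network"
        if config.stages.get("network") and lipid_cols:
            ncfg = config.network
            adj = pnet.signed_adjacency(
                panel[lipid_cols], beta=ncfg.get("beta", pnet.DEFAULT_BETA)
            )
            dissim = pnet.topological_overlap(adj)
            partition = pnet.detect_modules(
                dissim,
                min_size=ncfg.get("min_size", pnet.DEFAULT_MIN_MODULE_SIZE),
                cut_height=ncfg.get("cut_height"),
            )
            _write_csv(
                partition.assignment.rename("module").rename_axis("lipid").reset_index(),
                outdir,
                "module_partition.csv",
                files,
            )
            me = pnet.module_eigenlipids(panel[lipid_cols], partition)
            me_frame = me.values.copy()
            me_frame.insert(0, "visit_index", panel["visit_index"].values)
            me_frame.insert(0, "child_id", panel["child_id"].values)
            _write_csv(me_frame, outdir, "eigenlipids.csv", files)
            if me.values.shape[1] >= 2:
                edges, order = pnet.module_network(me)
                _write_csv(edges, outdir, "module_edges.csv", files)
                _write_json(
                    {"order": order, "variance_explained": me.variance_explained},
                    outdir,
                    "module_summary.json",
                    files,
                )
            # estimated eigenlipids replace any simulated latent signals
            panel = panel.drop(columns=me_cols)
            panel = pd.concat([panel.reset_index(drop=True), me.values.reset_index(drop=True)], axis=1)
            me_cols = list(me.values.columns)
            manifest.stage_info["network"] = {
                "n_lipids": len(lipid_cols),
                "n_modules": len(partition.module_labels),
                "n_unassigned": int((partition.assignment == 0).sum()),
            }

        growth_cols = [c for c in pio.GROWTH_COLUMNS if c in panel.columns]

        # ---- panel models ----
        current_stage = "panel"
        if config.stages.get("panel"):
            alpha = config.panel.get("alpha", 0.05)
            trends = []
            for gv in growth_cols:
                fit = ppanel.within_fe_fit(panel, gv, ["visit_index"])
                trends.append(
                    {
                        "response": gv,
                        "beta": fit.coef("visit_index"),
                        "pvalue": fit.pvalue("visit_index"),
                        "n_obs": fit.n_obs,
                        "n_children": fit.n_children,
                    }
                )
            _write_csv(pd.DataFrame(trends), outdir, "growth_trends.csv", files)
            if lipid_cols:
                screen = ppanel.trend_screen(panel, lipid_cols, alpha=alpha)
                _write_csv(
                    screen.table.rename_axis("lipid").reset_index(),
                    outdir,
                    "lipid_trends.csv",
                    files,
                )
            if me_cols:
                assoc_rows = []
                for gv in growth_cols:
                    for mc in me_cols:
                        fit = ppanel.within_fe_fit(panel, gv, ["visit_index", mc])
                        assoc_rows.append(
                            {
                                "response": gv,
                                "module": mc,
                                "coef": fit.coef(mc),
                                "pvalue": fit.pvalue(mc),
                            }
                        )
                assoc = pd.DataFrame(assoc_rows)
                assoc["fdr_pvalue"] = np.concatenate(
                    [
                        ppanel.bh_fdr(assoc.loc[assoc.response == gv, "pvalue"].values)
                        for gv in growth_cols
                    ]
                )
                _write_csv(assoc, outdir, "me_associations.csv", files)
                ttests = ppanel.consecutive_paired_ttests(panel, me_cols)
                _write_csv(ttests, outdir, "me_ttests.csv", files)
            manifest.stage_info["panel"] = {"n_growth": len(growth_cols)}

        # ---- latent classes ----
        current_stage = "lcmm"
        if config.stages.get("lcmm") and growth_cols:
            lcfg = config.lcmm
            response = lcfg.get("response", "laz")
            k_range = lcfg.get("k_range", [2, 3, 4])
            em = plcmm.EMConfig(
                n_restarts=lcfg.get("n_restarts", 5),
                tol=lcfg.get("tol", 1e-6),
                max_iter=lcfg.get("max_iter", 200),
                seed=config.seed,
            )
            best, table = plcmm.select_num_classes(
                panel, response, k_range=k_range, config=em
            )
            _write_csv(table.reset_index(), outdir, "lcmm_criteria.csv", files)
            _write_csv(
                best.posterior.rename_axis("child_id").reset_index(),
                outdir,
                "lcmm_posteriors.csv",
                files,
            )
            _write_json(
                {
                    "response": response,
                    "k": best.k,
                    "mixing": best.mixing.tolist(),
                    "trajectories": best.trajectories.tolist(),
                    "resid_sd": best.resid_sd,
                    "re_cov": best.re_cov.tolist(),
                    "loglik": best.loglik,
                    "aic": best.aic,
                    "converged": best.converged,
                },
                outdir,
                "lcmm_summary.json",
                files,
            )
            manifest.stage_info["lcmm"] = {"best_k": best.k}

        # ---- PVAR ----
        current_stage = "pvar"
        if config.stages.get("pvar") and growth_cols:
            pcfg = dict(config.pvar)
            alpha = pcfg.pop("alpha", 0.05)
            endog = pcfg.pop("endog", growth_cols + me_cols)
            exog = pcfg.pop("exog", ["sex"] if "sex" in panel.columns else [])
            spec = ppvar.PVARSpec(endog=endog, exog=exog, **pcfg)
            model = ppvar.fit_pvar(panel, spec)
            _write_csv(model.coef_table, outdir, "pvar_coefficients.csv", files)
            _write_json(
                {
                    "endog": endog,
                    "lags": spec.lags,
                    "transform": spec.transform,
                    "system": spec.system,
                    "hansen_j": model.hansen_j,
                    "hansen_df": model.hansen_df,
                    "hansen_p": model.hansen_p,
                    "n_instruments": model.n_instruments,
                    "n_children": model.n_children,
                    "eigenvalue_moduli": np.abs(model.eigenvalues).tolist(),
                    "stable": model.stable,
                },
                outdir,
                "pvar_model.json",
                files,
            )
            net = ppvar.extract_temporal_network(model, alpha=alpha)
            _write_csv(net.edges, outdir, "temporal_edges.csv", files)
            _write_json(net.to_node_link(), outdir, "temporal_network.json", files)
            manifest.stage_info["pvar"] = {
                "stable": model.stable,
                "n_edges": len(net.edges),
            }
    except Exception as err:  # noqa: BLE001 - abort with stage attribution
        manifest.failed_stage = current_stage
        manifest.finished = time.time()
        manifest.to_json(os.path.join(outdir, "manifest.json"))
        raise PipelineError(current_stage, err) from err

    manifest.finished = time.time()
    manifest_path = os.path.join(outdir, "manifest.json")
    manifest.files = sorted(os.path.relpath(p, outdir) for p in files)
    manifest.to_json(manifest_path)
    return manifest
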