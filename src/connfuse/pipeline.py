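"""End-to-end orchestration: simulate -> QC -> connectome -> univariate ->
classification -> consensus -> report.

All randomness flows from a single root seed through named substreams; a
run manifest records the configuration snapshot, per-stage output paths and
SHA-256 checksums, so re-running an identical configuration reproduces
byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
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
from .cohort_sim import CohortConfig, CovariateModel, MotionModel, cohort_arrays, simulate_cohort
from .connectome import (
    EdgeIndex,
    correct_functional,
    corrected_volumes,
    functional_network,
    permutation_test_structural,
    structural_network,
)
from .cv_consensus import CvConfig, extract_consensus, nested_cv
from .group_stats import edge_ttests, oneway_anova, partial_correlation, summation_score
from .ts_qc import preprocess_subject

logger = logging.getLogger("connfuse")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {paths, checksums, secs}

    def record(self, stage: str, paths: list[str], seconds: float) -> None:
        self.stages[stage] = {
            "paths": [os.path.basename(p) for p in paths],
            "checksums": {os.path.basename(p): _sha256(p) for p in paths},
            "seconds": round(seconds, 3),
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_CONFIG: dict = {
    "cohort": {},  # CohortConfig field overrides
    "qc": {
        "n_discard": 10,
        "fd_threshold_mm": 0.5,
        "global_sd_threshold": 2.0,
        "exclusion_fraction": 0.2,
        "band_hz": [0.01, 0.08],
    },
    "permutation": {"n_perm": 10000, "enabled": True},
    "cv": {},  # CvConfig field overrides
}


def load_config(path: str | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        for key, val in user.items():
            if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _cohort_config(cfg: dict, seed: int) -> CohortConfig:
    over = dict(cfg.get("cohort") or {})
    if isinstance(over.get("covariate_model"), dict):
        over["covariate_model"] = CovariateModel(**over["covariate_model"])
    if isinstance(over.get("motion_model"), dict):
        over["motion_model"] = MotionModel(**over["motion_model"])
    if isinstance(over.get("planted_edges"), list):
        over["planted_edges"] = tuple(tuple(e) for e in over["planted_edges"])
    if isinstance(over.get("structural_effect"), list):
        over["structural_effect"] = tuple(tuple(e) for e in over["structural_effect"])
    over.setdefault("seed", seed)
    return CohortConfig(**over)


def run_pipeline(config: dict | str | None, outdir: str, seed: int = 0) -> RunManifest:
    """Execute the full analysis; writes TSV/JSON artifacts plus a manifest.

    Returns the populated :class:`RunManifest`.  Stage failures raise
    :class:`StageError` naming the stage.
    """
    cfg = load_config(config) if (config is None or isinstance(config, str)) else config
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=_jsonable(cfg), seed=seed, version=__version__)
    report: dict = {"seed": seed, "version": __version__}

    stage = "simulate"
    try:
        t0 = time.time()
        ccfg = _cohort_config(cfg, seed)
        subjects = simulate_cohort(ccfg)
        idx = EdgeIndex(ccfg.n_regions)
        logger.info("simulated %d subjects", len(subjects))
        manifest.record(stage, [], time.time() - t0)

        stage = "qc"
        t0 = time.time()
        qc = cfg["qc"]
        kept, qc_rows, clean_ts = [], [], []
        for s in subjects:
            res = preprocess_subject(
                s.roi_timeseries,
                s.motion_params,
                s.nuisance_signals,
                n_discard=int(qc["n_discard"]),
                tr_seconds=ccfg.tr_seconds,
                fd_threshold_mm=float(qc["fd_threshold_mm"]),
                global_sd_threshold=float(qc["global_sd_threshold"]),
                exclusion_fraction=float(qc["exclusion_fraction"]),
                band_hz=tuple(qc["band_hz"]),
            )
            qc_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "mean_fd": res.report.mean_fd,
                    "n_scrubbed": res.report.n_scrubbed,
                    "excluded": res.report.excluded,
                }
            )
            if not res.report.excluded:
                kept.append(s)
                clean_ts.append(res.timeseries)
        qc_df = pd.DataFrame(qc_rows)
        qc_path = os.path.join(outdir, "qc_report.tsv")
        qc_df.to_csv(qc_path, sep="\t", index=False)
        report["n_excluded"] = int(qc_df["excluded"].sum())
        report["n_subjects_analyzed"] = len(kept)
        report["mean_fd_patients"] = float(qc_df.loc[qc_df.group > 0, "mean_fd"].mean())
        report["mean_fd_controls"] = float(qc_df.loc[qc_df.group <= 0, "mean_fd"].mean())
        manifest.record(stage, [qc_path], time.time() - t0)

        stage = "connectome"
        t0 = time.time()
        labels, volumes, covs = cohort_arrays(kept)
        vols_corr = corrected_volumes(volumes, covs)
        func_raw = np.vstack([functional_network(ts, idx) for ts in clean_ts])
        func_corr = correct_functional(func_raw, covs)
        net_a = structural_network(vols_corr[labels > 0], +1, idx)
        net_b = structural_network(vols_corr[labels <= 0], -1, idx)
        func_path = os.path.join(outdir, "functional_edges_corrected.tsv")
        pd.DataFrame(func_corr, columns=idx.edge_labels()).to_csv(
            func_path, sep="\t", index=False
        )
        struct_path = os.path.join(outdir, "structural_edges_groups.tsv")
        pd.DataFrame(
            {
                "connection": idx.edge_labels(),
                "r_patients": net_a.edge_vector,
                "r_controls": net_b.edge_vector,
            }
        ).to_csv(struct_path, sep="\t", index=False)
        manifest.record(stage, [func_path, struct_path], time.time() - t0)

        stage = "univariate"
        t0 = time.time()
        table = edge_ttests(func_corr, labels, idx)
        uni_path = os.path.join(outdir, "edge_ttests.tsv")
        table.to_csv(uni_path, sep="\t", index=False)
        report["n_significant_edges_fdr"] = int(table["significant"].sum())

        paths = [uni_path]
        if ccfg.planted_edges:
            pos = ccfg.planted_positions(idx)
            score = summation_score(func_corr, pos)
            groups = np.array(
                [s.episode if s.group > 0 else "control" for s in kept], dtype=object
            )
            anova = oneway_anova(score, groups)
            report["anova_F"] = anova.f
            report["anova_p"] = anova.p
            report["tukey_p"] = {f"{a} vs {b}": p for (a, b), p in anova.tukey_p.items()}
            pat = labels > 0
            hamd = np.array([s.clinical_scores.get("HAMD", np.nan) for s in kept])[pat]
            dur = np.array(
                [s.covariates.get("illness_duration", np.nan) for s in kept]
            )[pat]
            r, p = partial_correlation(score[pat], hamd, dur)
            report["partial_r_HAMD"] = r
            report["partial_p_HAMD"] = p
            anova_path = os.path.join(outdir, "episode_anova.json")
            with open(anova_path, "w") as fh:
                json.dump(
                    {
                        "groups": [str(g) for g in anova.group_names],
                        "means": anova.means.tolist(),
                        "sds": anova.sds.tolist(),
                        "ns": anova.ns.tolist(),
                        "F": anova.f,
                        "p": anova.p,
                    },
                    fh,
                    indent=2,
                )
            paths.append(anova_path)
        manifest.record(stage, paths, time.time() - t0)

        stage = "permutation"
        paths = []
        if cfg["permutation"].get("enabled", True):
            t0 = time.time()
            p_perm = permutation_test_structural(
                vols_corr[labels > 0],
                vols_corr[labels <= 0],
                n_perm=int(cfg["permutation"]["n_perm"]),
                seed=seed,
                edge_index=idx,
            )
            perm_path = os.path.join(outdir, "structural_permutation.tsv")
            pd.DataFrame({"connection": idx.edge_labels(), "p": p_perm}).to_csv(
                perm_path, sep="\t", index=False
            )
            from .group_stats import bh_adjust

            report["n_significant_structural_fdr"] = int(np.sum(bh_adjust(p_perm) < 0.05))
            manifest.record(stage, [perm_path], time.time() - t0)

        stage = "classify"
        t0 = time.time()
        cv_cfg = CvConfig(**{"seed": seed, **(cfg.get("cv") or {})})
        cv = nested_cv(func_corr, vols_corr, labels, cv_cfg, idx)
        report["cv_accuracy"] = cv.accuracy
        report["cv_sensitivity"] = cv.sensitivity
        report["cv_specificity"] = cv.specificity
        report["cv_auc"] = cv.auc
        rounds_path = os.path.join(outdir, "cv_rounds.tsv")
        cv.round_metrics.to_csv(rounds_path, sep="\t", index=False)
        manifest.record(stage, [rounds_path], time.time() - t0)

        stage = "consensus"
        t0 = time.time()
        cset = extract_consensus(cv.summed_abs_w, idx)
        conn_path = os.path.join(outdir, "consensus_connections.tsv")
        elabels = idx.edge_labels()
        pd.DataFrame(
            {
                "connection": [elabels[e] for e in cset.connections],
                "score": cset.connection_scores,
                "normalized_ability": cset.connection_ability,
            }
        ).to_csv(conn_path, sep="\t", index=False)
        node_path = os.path.join(outdir, "consensus_nodes.tsv")
        pd.DataFrame(
            {
                "region": [idx.region_labels[r] for r in cset.nodes],
                "score": cset.node_scores,
                "normalized_ability": cset.node_ability,
            }
        ).to_csv(node_path, sep="\t", index=False)
        report["consensus_connections"] = [elabels[e] for e in cset.connections]
        report["consensus_nodes"] = [idx.region_labels[r] for r in cset.nodes]
        manifest.record(stage, [conn_path, node_path], time.time() - t0)

        stage = "report"
        t0 = time.time()
        report_path = os.path.join(outdir, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest.record(stage, [report_path], time.time() - t0)
        manifest.write(os.path.join(outdir, "manifest.json"))
    except StageError:
        raise
    except Exception as exc:  # halt with the stage name
        raise StageError(stage, str(exc)) from exc
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
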