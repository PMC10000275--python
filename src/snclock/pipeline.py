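"""End-to-end orchestration: simulate/load -> QC -> normalize -> correct ->
screen -> clock -> consensus, with a reproducible run manifest.

A single global seed fans out to fixed per-stage offsets so each stage is
independently reproducible. Every intermediate artifact is written as
tab-delimited text; the manifest records parameters, per-stage record counts
and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .batchfix import combat_cpm, pca_diagnostic
from .clock import ENSEMBLE_METHODS, CVResult, ModelSpec, fit_predict_cv, stratified_age_folds
from .consensus import METHOD_COLUMNS, importance_ranks, rank_sum_core
from .datagen import SimConfig, generate_cohort, inject_qc_failures
from .micscreen import MineParams, screen
from .preprocess import (
    AgeGrouping,
    DetectionRule,
    QCThresholds,
    cpm,
    composition_summary,
    detection_filter,
    qc_filter,
    tmm_factors,
)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

log = logging.getLogger("snclock")

STAGES = ("simulate", "qc", "normalize", "detect", "correct", "screen", "clock", "consensus")

# per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 11, "qc_inject": 23, "folds": 37}


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; see the module docstring for stage order."""

    outdir: str = "snclock_run"
    seed: int = 0
    counts_path: str | None = None  # file mode; None -> simulate
    meta_path: str | None = None
    sim: SimConfig | None = None
    qc_fail_fraction: float = 0.0  # simulation mode: degrade this sample fraction below QC
    qc: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    grouping: AgeGrouping = dataclasses.field(default_factory=AgeGrouping)
    detection: DetectionRule = dataclasses.field(default_factory=DetectionRule)
    use_tmm: bool = True
    batch_correct: bool = True
    mine: MineParams = dataclasses.field(default_factory=MineParams)
    screen_threshold: float = 0.7
    methods: tuple = ("linear_regression", "elastic_net") + ENSEMBLE_METHODS
    n_estimators: int = 100
    k_folds: int = 5
    top_n_core: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "sim":
                kwargs["sim"] = SimConfig(**value)
            elif key == "qc":
                kwargs["qc"] = QCThresholds(**value)
            elif key == "grouping":
                kwargs["grouping"] = AgeGrouping(
                    {g: tuple(float("inf") if v == "inf" else v for v in iv) for g, iv in value.items()}
                )
            elif key == "detection":
                kwargs["detection"] = DetectionRule(**value)
            elif key == "mine":
                kwargs["mine"] = MineParams(**value)
            elif key == "methods":
                kwargs["methods"] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json).

    Any stage error aborts the run: partial outputs stay on disk and the
    manifest is written with a FAILED marker naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "qc": dataclasses.asdict(config.qc),
            "detection": dataclasses.asdict(config.detection),
            "mine": dataclasses.asdict(config.mine),
            "screen_threshold": config.screen_threshold,
            "use_tmm": config.use_tmm,
            "batch_correct": config.batch_correct,
            "methods": list(config.methods),
            "n_estimators": config.n_estimators,
            "k_folds": config.k_folds,
        },
        "stages": [],
        "files": {},
    }
    state: dict = {}

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"].append({"stage": stage, "status": status, **info})
        log.info("[%s] %s %s", stage, status, info)

    def save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        if index:
            sio.write_table(df, path, index=True)
        else:
            sio.write_table(df, path, index=False)
        manifest["files"][name] = _sha256(path)

    t0 = time.time()
    stage = "simulate"
    try:
        if config.counts_path:
            counts = sio.read_matrix(config.counts_path)
            meta = sio.read_meta(config.meta_path)
            truth = None
            record("simulate", "PASSED", mode="load", genes=len(counts), samples=counts.shape[1])
        else:
            sim = config.sim or SimConfig(seed=config.seed + SEED_OFFSETS["simulate"])
            counts, meta, truth = generate_cohort(sim)
            if config.qc_fail_fraction:
                meta = inject_qc_failures(
                    meta, config.qc_fail_fraction, config.seed + SEED_OFFSETS["qc_inject"]
                )
            save("counts.tsv", counts)
            save("truth_genes.tsv", truth.genes)
            record("simulate", "PASSED", mode="simulate", genes=len(counts), samples=counts.shape[1])
        sio.write_meta(meta, out / "meta.tsv")
        manifest["files"]["meta.tsv"] = _sha256(out / "meta.tsv")

        stage = "qc"
        kept, audit = qc_filter(meta, config.qc)
        save("qc_audit.tsv", audit)
        if not kept:
            raise ValueError("no samples remain after QC")
        counts = counts[kept]
        meta = meta.loc[kept]
        record("qc", "PASSED", retained=len(kept), removed=int((~audit["retained"]).sum()))

        stage = "normalize"
        lib = meta["total_reads"]
        factors = tmm_factors(counts, lib_sizes=lib) if config.use_tmm else None
        expr = cpm(counts, factors=factors, lib_sizes=lib)
        save("cpm.tsv", expr)
        record("normalize", "PASSED", tmm=config.use_tmm)

        stage = "detect"
        expressed = detection_filter(expr, meta, config.grouping, config.detection)
        if not expressed:
            raise ValueError("no genes pass the detection filter")
        expr = expr.loc[expressed]
        comp = composition_summary(
            expr,
            truth.genes["biotype"] if truth is not None else pd.Series("unknown", index=expr.index),
            meta,
            config.grouping,
        )
        save("composition.tsv", comp, index=False)
        record("detect", "PASSED", expressed=len(expressed))

        stage = "correct"
        if config.batch_correct:
            corrected, model = combat_cpm(expr, meta["batch"])
            _, before = pca_diagnostic(np.log2(expr + 1.0), meta)
            _, after = pca_diagnostic(corrected, meta)
            record(
                "correct",
                "PASSED",
                pc1_batch_r2_before=round(before["pc1_batch_r2"], 4),
                pc1_batch_r2_after=round(after["pc1_batch_r2"], 4),
            )
        else:
            corrected = np.log2(expr + 1.0)
            record("correct", "SKIPPED", note="screen consumes the CPM matrix directly")
        save("corrected.tsv", corrected)

        stage = "screen"
        if corrected.shape[1] == 0:
            raise ValueError("no samples remain")
        assoc, selected = screen(
            corrected, meta["age"].to_numpy(), config.screen_threshold, config.mine
        )
        save("association.tsv", assoc)
        if not selected:
            raise ValueError("no genes pass the MIC/TIC screen")
        record("screen", "PASSED", tested=len(assoc), selected=len(selected))

        stage = "clock"
        folds = stratified_age_folds(
            meta, config.k_folds, config.grouping, config.seed + SEED_OFFSETS["folds"]
        )
        features = corrected.loc[selected]
        results: dict[str, CVResult] = {}
        metrics_rows = []
        for method in config.methods:
            spec = ModelSpec(method=method, n_estimators=config.n_estimators, seed=config.seed)
            res = fit_predict_cv(features, meta["age"].to_numpy(), spec, folds)
            results[method] = res
            metrics_rows.append(
                {"method": method, "r2": res.r2, "rmse": res.rmse, "mae": res.mae}
            )
        metrics = pd.DataFrame(metrics_rows).set_index("method")
        save("clock_metrics.tsv", metrics)
        imp = pd.DataFrame(
            {m: results[m].importance for m in config.methods if results[m].importance is not None}
        )
        save("importances.tsv", imp)
        record("clock", "PASSED", methods=len(config.methods), features=len(selected))

        stage = "consensus"
        ranks = {
            METHOD_COLUMNS[m]: importance_ranks(results[m].importance)
            for m in ENSEMBLE_METHODS
            if m in results and results[m].importance is not None
        }
        table = rank_sum_core(ranks, top_n=config.top_n_core)
        save("consensus.tsv", table)
        record("consensus", "PASSED", core=int(table["core"].sum()))

        manifest["status"] = "PASSED"
        state.update(
            counts=counts, meta=meta, truth=truth, expr=expr, corrected=corrected,
            association=assoc, selected=selected, results=results, consensus=table,
            metrics=metrics,
        )
    except Exception as exc:
        record(stage, "FAILED", error=str(exc))
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["_state"] = state  # in-memory only; not serialized
    return manifest


def report(manifest: dict) -> str:
    """Human-readable run summary: stages, metrics and the top consensus table."""
    lines = ["snclock run report", "==================", f"status: {manifest.get('status')}"]
    for s in manifest["stages"]:
        extra = {k: v for k, v in s.items() if k not in ("stage", "status")}
        lines.append(f"  {s['stage']:<10} {s['status']:<8} {extra}")
    state = manifest.get("_state", {})
    metrics = state.get("metrics")
    if metrics is not None:
        lines.append("\nclock metrics (out-of-fold averages):")
        lines.append(metrics.round(4).to_string())
    table = state.get("consensus")
    if table is None or not table["core"].any():
        lines.append("\nconsensus: no core genes identified")
    else:
        top = table[table["core"]].head(10)
        lines.append("\ntop core age-related genes (rank sum ascending):")
        lines.append(top.to_string())
    return "\n".join(lines)
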