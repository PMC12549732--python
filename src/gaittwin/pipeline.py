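"""End-to-end orchestration: simulate -> extract -> twin -> analyze.

A run writes everything under one output directory:

    cohort.csv                  clinical table
    trials/<child_id>.csv/.json raw signals + ground-truth sidecars
    metrics.csv                 one metric vector per child
    twins/<pseudonym>.json      FHIR-flavoured bundles
    twins/cohort.ttl            canonical Turtle for the cohort
    twins/kg_edges.csv          knowledge-graph edge list
    analysis/*.json|csv         cluster / classification / attribution reports
    run_log.jsonl               structured per-stage log

Every artifact's metadata carries the config hash and master seed, so any
number in any report is traceable to (config, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .analysis import (MODEL_NAMES, feature_attribution, impute,
                       kmeans_repeated, minmax_scale, train_and_evaluate)
from .cohort import (ChildRecord, CohortSpec, generate_cohort, read_cohort_csv,
                     write_cohort_csv)
from .complexity import ComplexityConfig
from .errors import ValidationError
from .events import EventConfig
from .features import CLINICAL_FEATURES, FEATURE_NAMES, extract_features, metrics_frame
from .gaitsim import GaitParams, generate_gait_trial, params_for_child, read_trial_csv, write_trial_csv
from .twin import build_twin, export_knowledge_graph, to_fhir_json, to_rdf_turtle


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    models: list[str] = Field(default_factory=lambda: list(MODEL_NAMES))
    split: float = 0.75
    cv_folds: int = 5
    n_iter: int = 15
    use_smote: bool = False
    cluster_runs: int = 30
    impute_strategy: str = "median"
    attribution_repeats: int = 10


class PipelineConfig(BaseModel):
    """Strict-schema configuration of a full run (unknown keys are errors)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    gait: GaitParams = Field(default_factory=GaitParams)
    events: EventConfig = Field(default_factory=EventConfig)
    complexity: ComplexityConfig = Field(default_factory=ComplexityConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    salt: str = "gaittwin"
    version: str = __version__

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


class RunLog:
    def __init__(self, path: Path, echo: bool = True):
        self.path = path
        self.echo = echo
        path.write_text("")

    def event(self, stage: str, **kw) -> None:
        rec = {"stage": stage, **kw}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
        if self.echo:
            print(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in kw.items()))


def simulate(cfg: PipelineConfig, out: Path, log: Optional[RunLog] = None
             ) -> list[ChildRecord]:
    """Generate cohort table and per-child gait trials."""
    cohort_spec = cfg.cohort.model_copy(update={"seed": cfg.seed})
    if cohort_spec.n_preterm + cohort_spec.n_fullterm == 0:
        raise ValidationError("cohort is empty: n_preterm + n_fullterm == 0")
    children = generate_cohort(cohort_spec)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(children, out / "cohort.csv")
    trials = out / "trials"
    trials.mkdir(exist_ok=True)
    for child in children:
        p = params_for_child(child, cohort_spec.effect_sizes, base=cfg.gait)
        trial = generate_gait_trial(child, p, seed=cfg.seed)
        write_trial_csv(trial, trials / f"{child.child_id}.csv")
    if log:
        log.event("simulate", n=len(children), out=str(out))
    return children


def extract(cfg: PipelineConfig, out: Path, log: Optional[RunLog] = None
            ) -> pd.DataFrame:
    """Run the metric battery on every stored trial."""
    children = read_cohort_csv(out / "cohort.csv")
    rows = []
    for child in children:
        csv_path = out / "trials" / f"{child.child_id}.csv"
        if not csv_path.exists():
            raise ValidationError(f"missing trial file for child {child.child_id}")
        trial = read_trial_csv(csv_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(extract_features(trial, child, cfg.events, cfg.complexity))
    df = metrics_frame(rows)
    df.insert(1, "config_hash", cfg.config_hash())
    df.to_csv(out / "metrics.csv", index=False)
    if log:
        log.event("extract", n=len(df), out=str(out / "metrics.csv"))
    return df


def build_twins(cfg: PipelineConfig, out: Path, log: Optional[RunLog] = None) -> int:
    """Write one FHIR-flavoured bundle per child plus cohort Turtle and KG."""
    children = read_cohort_csv(out / "cohort.csv")
    metrics = pd.read_csv(out / "metrics.csv")
    tdir = out / "twins"
    tdir.mkdir(exist_ok=True)
    docs = []
    created = "1970-01-01T00:00:00+00:00"    # fixed for byte-reproducibility
    for child in children:
        row = metrics[metrics.child_id == child.child_id]
        mrow = row.iloc[0].to_dict() if len(row) else None
        doc = build_twin(child, mrow, salt=cfg.salt,
                        config_hash=cfg.config_hash(), created=created)
        (tdir / f"{doc.subject}.json").write_text(to_fhir_json(doc))
        docs.append(doc)
    ttl = "".join(to_rdf_turtle(d) for d in docs)
    (tdir / "cohort.ttl").write_text(ttl)
    kg_ttl, edges = export_knowledge_graph(docs)
    (tdir / "kg.ttl").write_text(kg_ttl)
    edges.to_csv(tdir / "kg_edges.csv", index=False)
    if log:
        log.event("twin", n=len(docs), out=str(tdir))
    return len(docs)


def analyze(cfg: PipelineConfig, out: Path, log: Optional[RunLog] = None) -> dict:
    """Clustering, classification over all configured learners, attribution."""
    metrics = pd.read_csv(out / "metrics.csv")
    adir = out / "analysis"
    adir.mkdir(exist_ok=True)
    X_raw = metrics[FEATURE_NAMES]
    y = metrics["risk"]

    X_imp, _ = impute(X_raw, cfg.analysis.impute_strategy)
    X_scaled, _ = minmax_scale(X_imp)
    cl = kmeans_repeated(X_scaled, runs=cfg.analysis.cluster_runs, seed=cfg.seed)
    # orient cluster 1 as the high-risk-enriched cluster
    high = (y == "high").to_numpy()
    rate1 = high[cl.consensus == 1].mean() if (cl.consensus == 1).any() else 0.0
    rate0 = high[cl.consensus == 0].mean() if (cl.consensus == 0).any() else 0.0
    high_cluster = 1 if rate1 >= rate0 else 0
    cluster_report = {
        "consensus": cl.consensus.tolist(),
        "high_risk_cluster": high_cluster,
        "high_risk_capture": float(high[cl.consensus == high_cluster].sum()
                                   / max(1, high.sum())),
        "importance_mean": cl.importance_mean.round(6).to_dict(),
        "importance_sd": cl.importance_sd.round(6).to_dict(),
    }
    pd.DataFrame({"importance_mean": cl.importance_mean,
                  "importance_sd": cl.importance_sd}).to_csv(adir / "cluster_importance.csv")

    reports = {}
    best_name, best_result = None, None
    for name in cfg.analysis.models:
        res = train_and_evaluate(X_raw, y, model_spec=name,
                                 split=cfg.analysis.split,
                                 cv_folds=cfg.analysis.cv_folds,
                                 seed=cfg.seed, use_smote=cfg.analysis.use_smote,
                                 n_iter=cfg.analysis.n_iter,
                                 impute_strategy=cfg.analysis.impute_strategy)
        reports[name] = {"confusion": [res.report.TP, res.report.FP,
                                       res.report.FN, res.report.TN],
                         **res.report.rounded(), "meta": res.report.search_meta}
        if log:
            log.event("classify", model=name, **res.report.rounded())
        if best_result is None or res.report.BA > best_result.report.BA:
            best_name, best_result = name, res

    attr = feature_attribution(best_result.estimator, best_result.X_test,
                               best_result.y_test,
                               repeats=cfg.analysis.attribution_repeats,
                               seed=cfg.seed)
    attr.to_csv(adir / "attribution.csv", index=False)

    summary = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
               "version": cfg.version, "cluster": cluster_report,
               "classification": reports, "best_model": best_name}
    (adir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if log:
        log.event("analyze", best=best_name, out=str(adir))
    return summary


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute all four stages in order; partial outputs survive a failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run_log.jsonl")
    stages = [("simulate", lambda: simulate(cfg, out, log)),
              ("extract", lambda: extract(cfg, out, log)),
              ("twin", lambda: build_twins(cfg, out, log)),
              ("analyze", lambda: analyze(cfg, out, log))]
    summary = None
    for name, fn in stages:
        t0 = time.time()
        try:
            result = fn()
        except Exception as e:
            log.event("failure", failed_stage=name, error=str(e))
            raise
        log.event("timing", timed_stage=name, seconds=round(time.time() - t0, 2))
        if name == "analyze":
            summary = result
    return summary


def make_fixtures(out_dir, seed: int = 2024) -> PipelineConfig:
    """Small 6-child cohort (2 high-risk expected by construction) with 20-s
    trials, used by the test suite. One child's cognitive score is removed to
    exercise imputation."""
    cfg = PipelineConfig(
        seed=seed,
        cohort=CohortSpec(n_preterm=4, n_fullterm=2,
                          ga_preterm_range=(23.0, 30.0), seed=seed),
        gait=GaitParams(duration_s=20.0),
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = simulate(cfg, out)
    # blank one cognitive score to exercise imputation downstream
    df = pd.read_csv(out / "cohort.csv")
    df.loc[df.index[0], "cog_score"] = None
    df.to_csv(out / "cohort.csv", index=False)
    extract(cfg, out)
    return cfg
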