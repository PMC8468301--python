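"""End-to-end orchestration: clean → anchor → MAP → forecast → evaluate → VPC.

A run is fully described by a :class:`RunConfig`; identical config + seed
give identical outputs. Each stage is pure (no stage mutates its inputs), so
any stage can be re-run from saved intermediates. Models that are
incompatible with the dataset (missing covariates) are skipped with a
recorded finding rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .data_io import (CleaningConfig, EventTable, apply_exclusion_cascade,
                      parse_event_table)
from .evaluation import (ClassificationConfig, EvaluationSummary,
                         PredictionRecord, evaluate_records,
                         stratify_predictions)
from .map_forecast import estimate_ebes, forecast, make_forecast_task
from .model_config import PopPKModel, load_model_spec, validate_against_dataset
from .synthetic_cohort import SyntheticCohortConfig, generate_cohort
from .vpc import VPCConfig, VPCResult, run_vpc

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ModelRunResult",
    "run_pipeline",
    "forecast_dataset",
    "gof_table",
    "records_to_frame",
    "frame_to_records",
]


@dataclass
class RunConfig:
    model_paths: Sequence[str | Path] = ()
    data_path: Optional[str | Path] = None
    cohort: Optional[SyntheticCohortConfig] = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    policy: str = "locf_at_anchor"
    target_trough: float = 5.0
    vpc: Optional[VPCConfig] = None
    seed: int = 0
    outdir: Optional[str | Path] = None

    def __post_init__(self) -> None:
        if self.data_path is None and self.cohort is None:
            self.cohort = SyntheticCohortConfig()


@dataclass
class ModelRunResult:
    model: PopPKModel
    records: list[PredictionRecord]
    summary: EvaluationSummary
    vpc: Optional[VPCResult] = None
    skipped: Optional[list[str]] = None


def forecast_dataset(model: PopPKModel, data: EventTable,
                     policy: str = "locf_at_anchor",
                     seed: int = 0, n_starts: int = 5) -> list[PredictionRecord]:
    """MAP-estimate and forecast every patient of a cleaned dataset."""
    records: list[PredictionRecord] = []
    for pid in data.patients():
        task = make_forecast_task(data, pid, policy=policy)
        if task is None:
            continue
        est = estimate_ebes(model, task, seed=seed, n_starts=n_starts)
        records.extend(forecast(model, est, task))
    return records


def run_pipeline(cfg: RunConfig) -> dict[str, ModelRunResult]:
    """Run the full evaluation for every model in the config."""
    if cfg.data_path is not None:
        raw = parse_event_table(cfg.data_path, allow_missing_dose_times=True)
    else:
        raw, _ = generate_cohort(cfg.cohort, seed=cfg.seed)
    clean, report = apply_exclusion_cascade(raw, cfg.cleaning)
    log.info("cleaning: %s", report.to_dict())

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "exclusion_report.json")
        clean.to_csv(outdir / "cleaned.csv")

    results: dict[str, ModelRunResult] = {}
    for path in cfg.model_paths:
        model = load_model_spec(path)
        findings = validate_against_dataset(model, clean)
        if findings:
            log.warning("skipping model %s: %s", model.name, "; ".join(findings))
            results[model.name] = ModelRunResult(model=model, records=[],
                                                 summary=EvaluationSummary(),
                                                 skipped=findings)
            continue
        records = forecast_dataset(model, clean, policy=cfg.policy, seed=cfg.seed)
        summary = evaluate_records(records, ClassificationConfig(cfg.target_trough))
        vpc_result = None
        if cfg.vpc is not None:
            vpc_result = run_vpc(model, clean,
                                 dataclasses.replace(cfg.vpc, seed=cfg.seed))
        results[model.name] = ModelRunResult(model=model, records=records,
                                             summary=summary, vpc=vpc_result)
        if outdir:
            records_to_frame(records).to_csv(outdir / f"{model.name}_pred.csv",
                                             index=False)
            payload = {"seed": cfg.seed, "policy": cfg.policy,
                       "target_trough": cfg.target_trough,
                       "summary": summary.to_dict()}
            if vpc_result is not None:
                payload["vpc"] = vpc_result.to_dict()
            (outdir / f"{model.name}_summary.json").write_text(
                json.dumps(payload, indent=2))
    return results


# -- tabular views -----------------------------------------------------------

def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[PredictionRecord]:
    out = []
    for _, r in df.iterrows():
        d = r.to_dict()
        if pd.isna(d.get("first_ada_days")):
            d["first_ada_days"] = None
        out.append(PredictionRecord(**{k: d[k] for k in (
            "patient_id", "time_days", "x", "y", "dt_anchor_days",
            "ada_patient", "ada_sample", "first_ada_days", "trough", "anchor")}))
    return out


def gof_table(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Long-format observed-vs-predicted table for goodness-of-fit plots.

    One row per prediction record with its ADA group and time stratum;
    anchor records are flagged so they can be drawn distinctly.
    """
    if not predictions:
        raise ValueError("no prediction records")
    strata = stratify_predictions(predictions)
    label = {}
    for group, layers in strata.items():
        for name, recs in layers.items():
            if name == "all_pred":
                continue
            for r in recs:
                label[id(r)] = (group, name)
    rows = []
    for r in predictions:
        group, stratum = label[id(r)]
        rows.append(dict(patient_id=r.patient_id, obs=r.x, pred=r.y,
                         group=group, stratum=stratum, anchor=r.anchor,
                         trough=r.trough, time_days=r.time_days))
    return pd.DataFrame(rows)


def plot_gof(table: pd.DataFrame, path=None, target_trough: float = 5.0):
    """Observed-vs-predicted scatter with identity line and target guide."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for (group, anchor), sub in table.groupby(["group", "anchor"]):
        color = "tab:pink" if group == "ada_positive" else "tab:cyan"
        marker = "^" if anchor else "o"
        ax.scatter(sub["obs"], sub["pred"], s=18, alpha=0.7, c=color,
                   marker=marker, label=f"{group}{' (anchor)' if anchor else ''}")
    lim = max(table["obs"].max(), table["pred"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=1)
    ax.axvline(target_trough, color="gray", ls="--", lw=0.8)
    ax.axhline(target_trough, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("observed [µg/mL]")
    ax.set_ylabel("individual predicted [µg/mL]")
    ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
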