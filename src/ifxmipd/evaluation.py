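"""Quantitative forecast evaluation: accuracy, bias, strata, classification.

Accuracy and bias are computed on the log accuracy ratio ln(y/x) of predicted
(y) over observed (x) concentrations, following Morley's robust symmetric
measures:

* median symmetric accuracy  ζ = 100·(exp(median |ln(y/x)|) − 1) — the
  typical unsigned percentage error; half of all absolute percentage errors
  lie below ζ.
* symmetric signed percentage bias
  SSPB = 100·sign(M)·(exp(|M|) − 1), M = median ln(y/x) — a median-based
  percentage bias that penalizes over- and under-prediction equally.

Both are invariant to rescaling of the concentration unit, and swapping
observations with predictions leaves ζ unchanged while flipping the sign of
SSPB. Since median(|z|) ≥ |median(z)|, ζ ≥ |SSPB| always.

Predictions are stratified by time after the anchor concentration and, for
patients who develop anti-drug antibodies (ADA), by time relative to the
first ADA-positive sample. Dose-escalation classification compares observed
and predicted trough concentrations against the 5 µg/mL target: a trough
below target means a dose escalation is needed (the "positive" class).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "ClassificationConfig",
    "EvaluationSummary",
    "median_symmetric_accuracy",
    "symmetric_signed_percentage_bias",
    "stratify_predictions",
    "classify_trough",
    "summarize_classification",
    "confusion_counts",
    "evaluate_records",
    "ADA_NEG_STRATA",
    "ADA_POS_STRATA",
]

DAYS_PER_MONTH = 30.0
DAYS_PER_6_MONTHS = 183.0

ADA_NEG_STRATA = ("<=1 month", "1-6 months", ">6 months", "all_pred")
ADA_POS_STRATA = ("before ADA+", "1st ADA+ <=1 month", ">1 month ADA+", "all_pred")


@dataclass(frozen=True)
class PredictionRecord:
    """One observed/predicted concentration pair with its strata context.

    Times are in days; ``first_ada_days`` is on the same absolute axis as the
    sample time (``time_days``), not relative to the anchor.
    """

    patient_id: object
    time_days: float
    x: float                      # observed, µg/mL
    y: float                      # predicted, µg/mL
    dt_anchor_days: float
    ada_patient: bool
    ada_sample: bool
    first_ada_days: Optional[float]
    trough: bool
    anchor: bool = False


@dataclass(frozen=True)
class ClassificationConfig:
    """Dose-escalation decision threshold on trough concentrations."""

    target_trough: float = 5.0

    def __post_init__(self) -> None:
        if self.target_trough <= 0:
            raise ValueError("target_trough must be > 0")


# -- symmetric accuracy / bias ----------------------------------------------

def _log_ratios(pairs: Iterable[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(list(pairs), float)
    if arr.size == 0:
        raise ValueError("no prediction pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log accuracy ratios require strictly positive x and y")
    return np.log(y / x)


def median_symmetric_accuracy(pairs: Iterable[tuple[float, float]]) -> float:
    """ζ in percent: 100·(exp(median |ln(y/x)|) − 1)."""
    q = _log_ratios(pairs)
    return 100.0 * (math.exp(float(np.median(np.abs(q)))) - 1.0)


def symmetric_signed_percentage_bias(pairs: Iterable[tuple[float, float]]) -> float:
    """SSPB in percent: 100·sign(M)·(exp(|M|) − 1) with M = median ln(y/x)."""
    m = float(np.median(_log_ratios(pairs)))
    return 100.0 * math.copysign(math.expm1(abs(m)), m) if m != 0 else 0.0


def _clean_pairs(records: Sequence[PredictionRecord]) -> list[tuple[float, float]]:
    pairs = []
    for r in records:
        if r.x > 0 and r.y > 0:
            pairs.append((r.x, r.y))
        else:
            log.warning("dropping non-positive pair for patient %s at t=%.1f d "
                        "(x=%g, y=%g)", r.patient_id, r.time_days, r.x, r.y)
    return pairs


# -- stratification ----------------------------------------------------------

def stratify_predictions(records: Sequence[PredictionRecord]
                         ) -> dict[str, dict[str, list[PredictionRecord]]]:
    """Assign records to the ADA-negative / ADA-positive strata.

    ADA-negative patients are stratified by time after the anchor
    concentration (≤1 month, 1–6 months, >6 months); ADA-positive patients by
    time relative to their first ADA-positive sample. ``all_pred`` pools all
    predictions of a group, excluding anchor records; anchor records are
    collected separately under ``cmap``.
    """
    out = {"ada_negative": {s: [] for s in ADA_NEG_STRATA},
           "ada_positive": {s: [] for s in ADA_POS_STRATA}}
    out["ada_negative"]["cmap"] = []
    out["ada_positive"]["cmap"] = []
    for r in records:
        group = "ada_positive" if r.ada_patient else "ada_negative"
        if r.anchor:
            out[group]["cmap"].append(r)
            continue
        out[group]["all_pred"].append(r)
        if not r.ada_patient:
            if r.dt_anchor_days <= DAYS_PER_MONTH:
                key = "<=1 month"
            elif r.dt_anchor_days <= DAYS_PER_6_MONTHS:
                key = "1-6 months"
            else:
                key = ">6 months"
        else:
            if r.first_ada_days is None:
                raise ValueError(
                    f"ADA-positive record for patient {r.patient_id} lacks first_ada_days")
            if r.time_days < r.first_ada_days:
                key = "before ADA+"
            elif r.time_days <= r.first_ada_days + DAYS_PER_MONTH:
                key = "1st ADA+ <=1 month"
            else:
                key = ">1 month ADA+"
        out[group][key].append(r)
    return out


# -- dose-escalation classification ------------------------------------------

def classify_trough(obs: float, pred: float,
                    cfg: ClassificationConfig | None = None) -> str:
    """Classify one trough pair; 'positive' = escalation needed (< target).

    Returns ``TP`` (both below target), ``TN`` (both at/above), ``FP``
    (predicted below, observed at/above) or ``FN`` (predicted at/above,
    observed below).
    """
    cfg = cfg or ClassificationConfig()
    thr = cfg.target_trough
    obs_pos = obs < thr
    pred_pos = pred < thr
    if pred_pos:
        return "TP" if obs_pos else "FP"
    return "FN" if obs_pos else "TN"


def summarize_classification(counts: Mapping[str, int]) -> float:
    """Classification accuracy in percent, rounded to one decimal."""
    total = sum(counts.get(k, 0) for k in ("TP", "FN", "TN", "FP"))
    if total == 0:
        raise ValueError("no classified trough pairs")
    acc = 100.0 * (counts.get("TP", 0) + counts.get("TN", 0)) / total
    return round(acc, 1)


def confusion_counts(records: Sequence[PredictionRecord],
                     cfg: ClassificationConfig | None = None
                     ) -> dict[str, dict[str, int]]:
    """TP/FN/TN/FP counts over trough predictions, split by sample ADA status."""
    cfg = cfg or ClassificationConfig()
    out = {"ada_negative": dict(TP=0, FN=0, TN=0, FP=0),
           "ada_positive": dict(TP=0, FN=0, TN=0, FP=0)}
    for r in records:
        if not r.trough or r.anchor:
            continue
        group = "ada_positive" if r.ada_sample else "ada_negative"
        out[group][classify_trough(r.x, r.y, cfg)] += 1
    return out


# -- full summary ------------------------------------------------------------

@dataclass
class EvaluationSummary:
    """Stratified ζ/SSPB plus dose-escalation confusion counts per ADA group."""

    zeta: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    sspb: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    n: dict[str, dict[str, int]] = field(default_factory=dict)
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)
    accuracy: dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"zeta_pct": self.zeta, "sspb_pct": self.sspb, "n": self.n,
                "dose_escalation": {"confusion": self.confusion,
                                    "accuracy_pct": self.accuracy}}


def evaluate_records(records: Sequence[PredictionRecord],
                     cfg: ClassificationConfig | None = None) -> EvaluationSummary:
    """Compute the full stratified evaluation of a prediction set."""
    cfg = cfg or ClassificationConfig()
    strata = stratify_predictions(records)
    summary = EvaluationSummary()
    for group, layers in strata.items():
        summary.zeta[group] = {}
        summary.sspb[group] = {}
        summary.n[group] = {}
        for name, recs in layers.items():
            pairs = _clean_pairs(recs)
            summary.n[group][name] = len(pairs)
            if pairs:
                summary.zeta[group][name] = median_symmetric_accuracy(pairs)
                summary.sspb[group][name] = symmetric_signed_percentage_bias(pairs)
            else:
                summary.zeta[group][name] = None
                summary.sspb[group][name] = None
    summary.confusion = confusion_counts(records, cfg)
    for group, counts in summary.confusion.items():
        total = sum(counts.values())
        summary.accuracy[group] = summarize_classification(counts) if total else None
    pooled = {k: summary.confusion["ada_negative"][k] + summary.confusion["ada_positive"][k]
              for k in ("TP", "FN", "TN", "FP")}
    summary.confusion["pooled"] = pooled
    summary.accuracy["pooled"] = (summarize_classification(pooled)
                                  if sum(pooled.values()) else None)
    return summary
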