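"""Virtual IBD cohorts for infliximab therapeutic-drug-monitoring studies.

The generator emulates the marginal structure of a routine-monitoring data
set of adult IBD patients on infliximab maintenance therapy: ~105 patients,
~5.5 mg/kg infusions roughly every 8 weeks, sparse sampling at interval
midpoints and troughs (median 2 samples per patient, range 1–12), about one
patient in five developing anti-drug antibodies, plus demographic and
laboratory covariates (weight, albumin, CRP, sex, diagnosis, concomitant
immunomodulators, Harvey–Bradshaw index, smoking). Only these marginal
summaries are matched; no attempt is made to reproduce any real patient.

Concentrations are simulated from a configurable generating population-PK
model with inter-individual variability, inter-occasion variability on
clearance, residual error, and a binary clearance increase from the moment
of ADA onset (onset drawn from an exponential hazard after the first dose).
The drawn random effects are returned as ground truth so estimation can be
validated against them.

A separate deterministic fixture reproduces the bookkeeping of a four-stage
exclusion cascade: 124 patients / 400 concentrations in, of which 11
patients (33 samples) have unusable dosing records, 3 samples are below the
quantification limit, 28 samples are pharmacokinetically implausible, and 8
patients end up with no informative sample — leaving 336 concentrations from
105 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .data_io import EventTable
from .map_forecast import individual_trajectory
from .model_config import PopPKModel, reference_model
from .pk_engine import DosingEvent, concentration_profile, simulate_observation

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_cascade_fixture",
]

HOURS_PER_WEEK = 168.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-design and population parameters of the virtual cohort.

    Defaults reproduce the target summary statistics: median dose 5.5
    (IQR 5.1–5.9) mg/kg, median interval 8.0 (IQR 7.7–8.6) weeks, weight
    median 70 kg (range 47–115), albumin median 4.35 g/dL, 48% female, 72%
    Crohn's disease, 16% on immunomodulators, 21% ADA-positive patients,
    samples per patient with median 2 on range 1–12.
    """

    n_patients: int = 105
    dose_per_kg_median: float = 5.5
    dose_per_kg_log_sd: float = 0.105      # matches the 5.1–5.9 IQR
    interval_weeks_median: float = 8.0
    interval_weeks_log_sd: float = 0.08    # matches the 7.7–8.6 IQR
    infusion_duration_h: float = 2.0
    samples_geometric_p: float = 0.35      # truncated 1..12 → median 2
    max_samples: int = 12
    max_occasions: int = 12
    ada_patient_prevalence: float = 0.21
    ada_onset_mean_days: float = 180.0
    ada_positive_threshold: float = 6.6
    ada_negative_level: float = 1.5        # U/mL, below assay LLOQ
    weight_median: float = 70.0
    weight_log_sd: float = 0.155           # matches the 59–80 IQR
    weight_range: tuple[float, float] = (47.0, 115.0)
    albumin_median: float = 4.35
    albumin_sd: float = 0.31
    albumin_range: tuple[float, float] = (2.53, 5.08)
    crp_median: float = 0.29
    crp_log_sd: float = 1.1
    crp_range: tuple[float, float] = (0.02, 7.49)
    female_fraction: float = 0.48
    cd_fraction: float = 0.72
    imm_fraction: float = 0.16
    smoking_probs: tuple[float, float, float, float] = (0.33, 0.39, 0.27, 0.01)
    model: Optional[PopPKModel] = None     # generating model; reference if None

    def __post_init__(self) -> None:
        for name in ("ada_patient_prevalence", "female_fraction",
                     "cd_fraction", "imm_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class GroundTruth:
    """True random effects and ADA onset per generated patient."""

    eta: dict[str, dict[str, float]] = field(default_factory=dict)
    kappa: dict[str, dict[int, float]] = field(default_factory=dict)
    ada_onset_h: dict[str, Optional[float]] = field(default_factory=dict)


def _trunc(rng, draw, lo, hi, max_tries=100):
    for _ in range(max_tries):
        v = draw(rng)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def _n_samples(rng, p, kmax):
    # geometric on 1..kmax (p=0.35 puts the median at 2)
    while True:
        k = int(rng.geometric(p))
        if 1 <= k <= kmax:
            return k


def generate_cohort(cfg: SyntheticCohortConfig | None = None,
                    seed: int = 0) -> tuple[EventTable, GroundTruth]:
    """Draw one virtual cohort; bit-identical for identical (cfg, seed)."""
    cfg = cfg or SyntheticCohortConfig()
    model = cfg.model or reference_model()
    rng = substream(seed, "cohort")
    omega = model.random.omega()
    truth = GroundTruth()
    rows = []

    for i in range(cfg.n_patients):
        pid = f"S{i + 1:04d}"
        wt = _trunc(rng, lambda r: cfg.weight_median * np.exp(r.normal(0, cfg.weight_log_sd)),
                    *cfg.weight_range)
        alb = _trunc(rng, lambda r: r.normal(cfg.albumin_median, cfg.albumin_sd),
                     *cfg.albumin_range)
        crp = _trunc(rng, lambda r: cfg.crp_median * np.exp(r.normal(0, cfg.crp_log_sd)),
                     *cfg.crp_range)
        sex = int(rng.random() < cfg.female_fraction)          # 1 = female
        diag = "CD" if rng.random() < cfg.cd_fraction else "UC"
        imm = int(rng.random() < cfg.imm_fraction)
        hbi = int(min(rng.geometric(0.4) - 1, 18))
        smok = ["never", "current", "past", "unknown"][
            int(rng.choice(4, p=cfg.smoking_probs))]

        dose_per_kg = cfg.dose_per_kg_median * np.exp(rng.normal(0, cfg.dose_per_kg_log_sd))
        amount = dose_per_kg * wt
        interval_h = (cfg.interval_weeks_median
                      * np.exp(rng.normal(0, cfg.interval_weeks_log_sd))) * HOURS_PER_WEEK

        n_obs = _n_samples(rng, cfg.samples_geometric_p, cfg.max_samples)
        occasions = np.sort(rng.choice(np.arange(cfg.max_occasions), size=n_obs,
                                       replace=True))
        sample_times, sample_types = [], []
        for occ in occasions:
            start = occ * interval_h
            if rng.random() < 0.5:
                frac, stype = rng.uniform(0.40, 0.60), "midpoint"
            else:
                frac, stype = rng.uniform(0.95, 0.995), "trough"
            sample_times.append(start + frac * interval_h)
            sample_types.append(stype)
        order = np.argsort(sample_times)
        sample_times = [sample_times[k] for k in order]
        sample_types = [sample_types[k] for k in order]
        n_doses = int(occasions.max()) + 2

        ada_positive = rng.random() < cfg.ada_patient_prevalence
        onset_h = None
        if ada_positive:
            # exponential hazard after the first dose, truncated to the
            # sampling window so positivity is observable in the data
            mean_h = cfg.ada_onset_mean_days * 24.0
            t_last = max(sample_times)
            u = rng.random()
            onset_h = -mean_h * np.log1p(-u * (1.0 - np.exp(-t_last / mean_h)))

        eta = rng.multivariate_normal(np.zeros(len(model.eta_names)), omega)
        eta_map = dict(zip(model.eta_names, map(float, eta)))
        kappa_map = {}
        if model.has_iov:
            sd = np.sqrt(model.random.iov_cl)
            kappa_map = {occ: float(rng.normal(0, sd)) for occ in range(n_doses)}

        doses = [DosingEvent(k * interval_h, amount, cfg.infusion_duration_h)
                 for k in range(n_doses)]
        dose_times = [d.time_h for d in doses]

        covs = {"WT": wt, "ALB": alb, "CRP": crp, "SEX": sex, "IMM": imm,
                "HBI": hbi}
        segs = [(0.0, {**covs, "ADA_POS": 0.0, "TIME": 0.0})]
        if onset_h is not None:
            segs.append((onset_h, {**covs, "ADA_POS": 1.0, "TIME": onset_h}))
        traj = individual_trajectory(model, segs, dose_times, eta_map, kappa_map)
        f = concentration_profile(doses, traj, sample_times, model.n_compartments)
        dv = simulate_observation(f, model.error, rng)

        truth.eta[pid] = eta_map
        truth.kappa[pid] = kappa_map
        truth.ada_onset_h[pid] = onset_h

        base = dict(ID=pid, WT=wt, ALB=alb, CRP=crp, SEX=sex, DIAG=diag,
                    IMM=imm, HBI=hbi, SMOK=smok)
        for d in doses:
            rows.append({**base, "TIME": d.time_h, "EVID": 1, "AMT": d.amount_mg,
                         "DUR": d.duration_h, "DV": np.nan, "MDV": 1,
                         "BLQ": False, "ADA": np.nan, "TYPE": np.nan})
        for t, stype, y in zip(sample_times, sample_types, np.atleast_1d(dv)):
            if onset_h is not None and t >= onset_h:
                ada = cfg.ada_positive_threshold + rng.lognormal(np.log(20.0), 1.0)
            else:
                ada = min(rng.lognormal(np.log(cfg.ada_negative_level), 0.4), 3.0)
            rows.append({**base, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DUR": np.nan, "DV": float(y), "MDV": 0,
                         "BLQ": bool(y < 0.00268), "ADA": ada, "TYPE": stype})

    table = EventTable(pd.DataFrame(rows), ada_threshold=cfg.ada_positive_threshold)
    return table, truth


# -- deterministic exclusion-cascade fixture ---------------------------------

def generate_cascade_fixture() -> EventTable:
    """124-patient / 400-concentration fixture exercising the full cascade.

    Engineered so the stages remove, in order: 11 patients with unusable
    dosing records (33 samples), 3 below-LLOQ samples, 28 implausible
    samples, and 8 patients left without an informative concentration —
    retaining 336 concentrations from 105 patients. Deterministic by
    construction (no randomness).
    """
    interval_h = 8 * HOURS_PER_WEEK      # 8-week intervals
    amount, dur = 385.0, 2.0             # 5.5 mg/kg × 70 kg
    base_cov = dict(WT=70.0, ALB=4.35, CRP=0.29, SEX=0, DIAG="CD", IMM=0,
                    HBI=1, SMOK="never")
    rows: list[dict] = []

    def dose_row(pid, t):
        return dict(ID=pid, TIME=t, EVID=1, AMT=amount, DUR=dur, DV=np.nan,
                    MDV=1, BLQ=False, ADA=np.nan, TYPE=np.nan, **base_cov)

    def obs_row(pid, t, dv, blq=False):
        return dict(ID=pid, TIME=t, EVID=0, AMT=np.nan, DUR=np.nan, DV=dv,
                    MDV=0, BLQ=blq, ADA=1.0, TYPE=np.nan, **base_cov)

    # retained patients: sample counts with median 2, range 1–12, total 336
    counts = [1] * 30 + [2] * 30 + [3] * 20 + [5] * 10 + [8] * 10 + [11] * 4 + [12]
    assert sum(counts) == 336 and len(counts) == 105
    pid_no = 0
    for k, n_obs in enumerate(counts):
        pid_no += 1
        pid = f"P{pid_no:03d}"
        for j in range(n_obs + 2):
            rows.append(dose_row(pid, j * interval_h))
        for j in range(n_obs):
            # one midpoint sample per interval, strictly decreasing over time
            t = j * interval_h + 28 * 24.0
            rows.append(obs_row(pid, t, 14.0 - 0.5 * j))
        if k < 28:
            # implausible extra sample: 8 days after the interval-0 sample,
            # not lower than it → removed as the later member of the pair
            rows.append(obs_row(pid, 28 * 24.0 + 8 * 24.0, 14.5))

    # 3 patients whose single sample is below the LLOQ (then uninformative)
    for _ in range(3):
        pid_no += 1
        pid = f"P{pid_no:03d}"
        rows.append(dose_row(pid, 0.0))
        rows.append(dose_row(pid, interval_h))
        rows.append(obs_row(pid, 28 * 24.0, 0.001, blq=True))

    # 5 patients with dosing records but no concentration samples
    for _ in range(5):
        pid_no += 1
        pid = f"P{pid_no:03d}"
        rows.append(dose_row(pid, 0.0))
        rows.append(dose_row(pid, interval_h))

    # 11 patients with unusable dosing information (a dose without a time),
    # carrying 3 samples each = 33 concentrations
    for _ in range(11):
        pid_no += 1
        pid = f"P{pid_no:03d}"
        rows.append(dose_row(pid, 0.0))
        rows.append(dose_row(pid, np.nan))
        for j in range(3):
            rows.append(obs_row(pid, j * interval_h + 28 * 24.0, 10.0 - j))

    return EventTable(pd.DataFrame(rows))
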