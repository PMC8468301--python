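"""Pharmacometric event tables: parsing, cleaning and covariate lookup.

The on-disk dialect is the NONMEM dataset convention (one row per event,
``ID/TIME/AMT/DUR/DV/EVID/MDV`` plus covariate columns). Internally all times
are hours since each patient's first record, doses are mg, and concentrations
are µg/mL.

The cleaning step implements a four-stage exclusion cascade typical of
therapeutic-drug-monitoring data sets:

1. patients with unusable dosing histories (a dose without a time stamp, or
   observations without any dose record) are dropped entirely;
2. observations below the assay's lower limit of quantification are dropped
   (the "M1" strategy);
3. pharmacokinetically implausible observations are dropped: within one dosing
   interval, a concentration that failed to decrease over a span of at least
   seven days cannot be explained by a linear-elimination model, so the later
   member of each violating pair is removed and the interval re-scanned;
4. patients left without a single quantifiable concentration are dropped.

Every removed record is attributed to exactly one stage, so retained + removed
always reconciles with the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "CleaningConfig",
    "ExclusionReport",
    "SchemaError",
    "RecordError",
    "parse_event_table",
    "write_event_table",
    "apply_exclusion_cascade",
    "covariate_value_at",
]

#: Columns with fixed meaning; anything else in a dataset is a covariate.
CORE_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "BLQ", "ADA", "TYPE"]

MANDATORY_COLUMNS = ["ID", "TIME", "EVID", "DV"]


class SchemaError(ValueError):
    """A dataset is missing mandatory structure."""


class RecordError(ValueError):
    """A single event row violates the dataset convention."""


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for the exclusion cascade.

    ``lloq_conc`` is the infliximab assay LLOQ (2.68 ng/mL expressed in
    µg/mL); ``ada_lloq`` and ``ada_positive_threshold`` are the anti-drug
    antibody assay LLOQ and clinical positivity cut-off in U/mL.
    """

    lloq_conc: float = 0.00268
    ada_lloq: float = 3.13
    ada_positive_threshold: float = 6.6
    implausibility_window_days: float = 7.0

    def __post_init__(self) -> None:
        for name in ("lloq_conc", "ada_lloq", "ada_positive_threshold",
                     "implausibility_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ada_positive_threshold < self.ada_lloq:
            raise ValueError("ada_positive_threshold must be >= ada_lloq")


@dataclass
class ExclusionReport:
    """Per-stage removal counts plus what survived the cascade."""

    missing_dosing_patients: int = 0
    missing_dosing_samples: int = 0
    blq_samples: int = 0
    implausible_samples: int = 0
    uninformative_patients: int = 0
    retained_patients: int = 0
    retained_samples: int = 0

    @property
    def removed_samples(self) -> int:
        return self.missing_dosing_samples + self.blq_samples + self.implausible_samples

    def to_dict(self) -> dict:
        d = asdict(self)
        d["removed_samples"] = self.removed_samples
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class EventTable:
    """One pharmacometric data set: dose and observation events plus covariates.

    Wraps a :class:`pandas.DataFrame` with the core columns above; extra
    columns are treated as (possibly time-varying) covariates. Rows are kept
    sorted by patient then time (missing dose times sort last within patient).
    """

    def __init__(self, df: pd.DataFrame, ada_threshold: float = 6.6):
        df = df.copy()
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        for col, default in (("AMT", np.nan), ("DUR", np.nan), ("MDV", 0),
                             ("BLQ", False), ("ADA", np.nan)):
            if col not in df.columns:
                df[col] = default
        df["BLQ"] = df["BLQ"].fillna(False).astype(bool)
        df["MDV"] = df["MDV"].fillna(0).astype(int)
        df = df.sort_values(["ID", "TIME"], kind="stable", na_position="last")
        self.df = df.reset_index(drop=True)
        self.ada_threshold = float(ada_threshold)
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        df = self.df
        obs = df[df["EVID"] == 0]
        t = obs["TIME"]
        if (t.dropna() < 0).any():
            raise RecordError("observation with negative time")
        doses = df[df["EVID"] == 1]
        bad_amt = doses["AMT"].notna() & (doses["AMT"] <= 0)
        if bad_amt.any():
            raise RecordError(f"dose row with non-positive amount (row {bad_amt.idxmax()})")
        neg_dv = obs["DV"].notna() & (obs["DV"] < 0)
        if neg_dv.any():
            raise RecordError(f"observation with negative concentration (row {neg_dv.idxmax()})")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    # -- patient-level views -------------------------------------------------

    def patients(self) -> list:
        return list(pd.unique(self.df["ID"]))

    @property
    def n_patients(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        """Number of concentration samples (observation rows with a DV)."""
        return int(((self.df["EVID"] == 0) & (self.df["MDV"] == 0)).sum())

    def patient(self, pid) -> pd.DataFrame:
        return self.df[self.df["ID"] == pid]

    def doses(self, pid) -> pd.DataFrame:
        p = self.patient(pid)
        return p[p["EVID"] == 1]

    def observations(self, pid, with_dv: bool = True) -> pd.DataFrame:
        p = self.patient(pid)
        obs = p[p["EVID"] == 0]
        if with_dv:
            obs = obs[obs["MDV"] == 0]
        return obs

    def dose_times(self, pid) -> np.ndarray:
        return np.sort(self.doses(pid)["TIME"].dropna().to_numpy(float))

    def occasion_of(self, pid, t: float) -> int:
        """Dosing-interval index of time ``t`` (interval k = [dose_k, dose_{k+1}))."""
        dt = self.dose_times(pid)
        return int(np.searchsorted(dt, t, side="right") - 1)

    # -- covariates ----------------------------------------------------------

    def covariate_value_at(self, pid, name: str, t: float,
                           policy: str = "full", anchor: float | None = None):
        """Last-observation-carried-forward covariate lookup.

        ``policy='full'`` uses the most recent measurement at or before ``t``;
        ``policy='locf_at_anchor'`` freezes the covariate at its value at
        ``anchor`` for any later time (the prospective-forecasting convention).

        ``ADA_POS`` is a derived binary covariate: the most recent anti-drug
        antibody measurement at or before the query time compared against the
        positivity threshold; a patient with no measurement yet counts as
        negative.
        """
        if policy not in ("full", "locf_at_anchor"):
            raise ValueError(f"unknown covariate policy {policy!r}")
        t_eff = t
        if policy == "locf_at_anchor":
            if anchor is None:
                raise ValueError("locf_at_anchor policy requires an anchor time")
            t_eff = min(t, anchor)
        if name == "ADA_POS":
            return float(self.ada_sample_positive(pid, t_eff))
        p = self.patient(pid)
        if name not in p.columns:
            raise KeyError(f"covariate {name!r} not in dataset (patient {pid})")
        rows = p[(p["TIME"].notna()) & (p["TIME"] <= t_eff) & p[name].notna()]
        if rows.empty:
            raise ValueError(
                f"no measurement of covariate {name!r} for patient {pid} at or before t={t_eff}")
        return rows.iloc[-1][name]

    # -- ADA status ----------------------------------------------------------

    def ada_sample_positive(self, pid, t: float) -> bool:
        """Sample-level ADA status: latest measurement at or before ``t``."""
        p = self.patient(pid)
        rows = p[(p["TIME"].notna()) & (p["TIME"] <= t) & p["ADA"].notna()]
        if rows.empty:
            return False
        return bool(rows.iloc[-1]["ADA"] > self.ada_threshold)

    def ada_patient_positive(self, pid) -> bool:
        """Patient-level ADA status: any measurement above threshold."""
        ada = self.patient(pid)["ADA"].dropna()
        return bool((ada > self.ada_threshold).any())

    def first_ada_time(self, pid) -> float | None:
        """Time (h) of the first ADA measurement above threshold, if any."""
        p = self.patient(pid)
        pos = p[p["ADA"].notna() & (p["ADA"] > self.ada_threshold)]
        if pos.empty:
            return None
        return float(pos["TIME"].iloc[0])

    # -- trough detection ----------------------------------------------------

    def is_trough(self, pid, t: float, window_h: float = 72.0) -> bool:
        """True if the sample sits at the end of a dosing interval.

        Uses the explicit ``TYPE`` column when present; otherwise a sample
        within ``window_h`` hours before the next dose counts as a trough.
        """
        p = self.patient(pid)
        if "TYPE" in p.columns:
            row = p[(p["EVID"] == 0) & (p["TIME"] == t)]
            if not row.empty and isinstance(row.iloc[0]["TYPE"], str):
                return row.iloc[0]["TYPE"] == "trough"
        dt = self.dose_times(pid)
        later = dt[dt > t]
        if later.size == 0:
            return False
        return bool(later[0] - t <= window_h)

    # -- export --------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"EventTable({self.n_patients} patients, "
                f"{self.n_observations} observations, {len(self.df)} rows)")


# -- parsing ----------------------------------------------------------------

def parse_event_table(path: str | Path, column_map: Mapping[str, str] | None = None,
                      dv_unit: str = "ug/mL", time_unit: str = "h",
                      allow_missing_dose_times: bool = False,
                      ada_threshold: float = 6.6) -> EventTable:
    """Read a NONMEM-convention CSV into an :class:`EventTable`.

    Parameters
    ----------
    column_map
        Optional mapping from file column names to the standard names
        (``ID, TIME, AMT, RATE, DUR, DV, EVID, MDV, BLQ, ADA`` + covariates).
    dv_unit
        ``'ug/mL'`` (stored as-is) or ``'ng/mL'`` (converted ×10⁻³).
    time_unit
        ``'h'`` or ``'day'`` (converted ×24).
    allow_missing_dose_times
        If False (default), a dose row without a time stamp is a
        :class:`RecordError`; if True such rows are kept so the exclusion
        cascade can attribute the patient to the missing-dosing stage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    for col in ("TIME", "AMT", "DV", "ADA"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if time_unit == "day":
        df["TIME"] = df["TIME"] * 24.0
    elif time_unit != "h":
        raise ValueError(f"unsupported time unit {time_unit!r}")
    if dv_unit == "ng/mL":
        df["DV"] = df["DV"] * 1e-3
    elif dv_unit != "ug/mL":
        raise ValueError(f"unsupported DV unit {dv_unit!r}")

    # Infusion duration: accept DUR directly or derive from RATE (amount/rate).
    if "DUR" not in df.columns and "RATE" in df.columns:
        rate = pd.to_numeric(df["RATE"], errors="coerce")
        df["DUR"] = df["AMT"] / rate
    if "RATE" in df.columns:
        df = df.drop(columns=["RATE"])

    if "MDV" not in df.columns:
        df["MDV"] = np.where((df["EVID"] == 0) & df["DV"].isna(), 1, 0)
    else:
        df["MDV"] = pd.to_numeric(df["MDV"], errors="coerce").fillna(0).astype(int)
    # An observation row with an empty DV is a missing-DV record, not an error.
    obs_missing = (df["EVID"] == 0) & df["DV"].isna() & (df["MDV"] == 0)
    df.loc[obs_missing, "MDV"] = 1

    if not allow_missing_dose_times:
        bad = (df["EVID"] == 1) & df["TIME"].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RecordError(f"dose row without time (file row {row + 2})")

    return EventTable(df, ada_threshold=ada_threshold)


def write_event_table(table: EventTable, path: str | Path) -> None:
    table.to_csv(path)


# -- exclusion cascade -------------------------------------------------------

def _sample_mask(df: pd.DataFrame) -> pd.Series:
    return (df["EVID"] == 0) & (df["MDV"] == 0)


def apply_exclusion_cascade(data: EventTable, cfg: CleaningConfig | None = None
                            ) -> tuple[EventTable, ExclusionReport]:
    """Apply the four-stage exclusion cascade; see the module docstring.

    Returns the cleaned table and a per-stage :class:`ExclusionReport`.
    An empty input yields an empty output with a zero report.
    """
    cfg = cfg or CleaningConfig()
    report = ExclusionReport()
    df = data.df.copy()
    if df.empty:
        return EventTable(df, ada_threshold=data.ada_threshold), report

    # Stage 1 — patients with unusable dosing records.
    drop_ids = []
    for pid, p in df.groupby("ID", sort=False):
        doses = p[p["EVID"] == 1]
        has_obs = bool(_sample_mask(p).any())
        if doses["TIME"].isna().any() or (has_obs and doses.empty):
            drop_ids.append(pid)
    if drop_ids:
        dropped = df[df["ID"].isin(drop_ids)]
        report.missing_dosing_patients = len(drop_ids)
        report.missing_dosing_samples = int(_sample_mask(dropped).sum())
        df = df[~df["ID"].isin(drop_ids)]

    # Stage 2 — BLQ observations (M1: discard).
    blq = _sample_mask(df) & (df["BLQ"] | (df["DV"] < cfg.lloq_conc))
    report.blq_samples = int(blq.sum())
    df = df[~blq]

    # Stage 3 — pharmacokinetically implausible observations.
    window_h = cfg.implausibility_window_days * 24.0
    drop_rows: list[int] = []
    for pid, p in df.groupby("ID", sort=False):
        dose_t = np.sort(p.loc[p["EVID"] == 1, "TIME"].dropna().to_numpy(float))
        obs = p[_sample_mask(p)]
        idx = obs.index.to_numpy()
        t = obs["TIME"].to_numpy(float)
        c = obs["DV"].to_numpy(float)
        occ = np.searchsorted(dose_t, t, side="right") - 1
        alive = np.ones(len(idx), bool)
        changed = True
        while changed:  # re-scan until no violating pair remains
            changed = False
            order = np.argsort(t, kind="stable")
            for a_pos in range(len(order)):
                i = order[a_pos]
                if not alive[i]:
                    continue
                for b_pos in range(a_pos + 1, len(order)):
                    j = order[b_pos]
                    if not alive[j] or occ[j] != occ[i]:
                        continue
                    if t[j] - t[i] >= window_h and c[j] >= c[i]:
                        alive[j] = False  # the later sample is discarded
                        changed = True
                if changed:
                    break
        drop_rows.extend(idx[~alive].tolist())
    report.implausible_samples = len(drop_rows)
    df = df.drop(index=drop_rows)

    # Stage 4 — patients left without an informative concentration.
    informative = df[_sample_mask(df)]["ID"].unique()
    uninformative = [pid for pid in pd.unique(df["ID"]) if pid not in set(informative)]
    report.uninformative_patients = len(uninformative)
    df = df[~df["ID"].isin(uninformative)]

    cleaned = EventTable(df.reset_index(drop=True), ada_threshold=data.ada_threshold)
    report.retained_patients = cleaned.n_patients
    report.retained_samples = cleaned.n_observations
    return cleaned, report


def covariate_value_at(data: EventTable, patient, name: str, t: float,
                       policy: str = "full", anchor: float | None = None):
    """Module-level alias for :meth:`EventTable.covariate_value_at`."""
    return data.covariate_value_at(patient, name, t, policy=policy, anchor=anchor)
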