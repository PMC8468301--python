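"""MAP Bayesian (empirical Bayes) estimation and forward forecasting.

The forecasting setting mirrors routine therapeutic drug monitoring: the
first retained concentration of a patient (the anchor, C_MAP) is used to
estimate the patient's random effects by maximum a posteriori (MAP)
estimation with population parameters fixed; all later concentrations are
then predicted from those empirical Bayes estimates (EBEs).

The MAP objective, with the η–ε interaction (residual variance evaluated at
the individual prediction f_j):

    OFV(η, κ) = Σ_j [ (y_j − f_j)² / g_j² + ln g_j² ]  +  ηᵀ Ω⁻¹ η  +  Σ_occ κ² / π²
    g_j² = σ_add² + σ_prop² · f_j²

Inter-occasion variability is included in the estimation (a κ for the
occasion carrying the anchor observation) but excluded from the individual
parameters used for prediction, which avoids propagating an occasion-specific
clearance shift into future occasions. Covariates after the anchor are
imputed by last observation carried forward (policy ``locf_at_anchor``) or
taken from their measured time courses (policy ``full``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from ._rng import substream
from .data_io import EventTable
from .evaluation import PredictionRecord
from .model_config import PopPKModel
from .pk_engine import DosingEvent, concentration_profile, individual_parameters

log = logging.getLogger(__name__)

__all__ = [
    "Observation",
    "ForecastTask",
    "IndividualEstimate",
    "covariate_segments",
    "individual_trajectory",
    "map_objective",
    "fit_random_effects",
    "estimate_ebes",
    "forecast",
    "make_forecast_task",
]


@dataclass(frozen=True)
class Observation:
    time_h: float
    conc: float
    occasion: int


@dataclass
class ForecastTask:
    """One patient's forecasting problem: anchor plus later target samples."""

    patient_id: object
    doses: list[DosingEvent]
    anchor: Observation
    targets: list[Observation]
    table: EventTable
    policy: str = "locf_at_anchor"

    def __post_init__(self) -> None:
        if self.policy not in ("locf_at_anchor", "full"):
            raise ValueError(f"unknown covariate policy {self.policy!r}")
        for t in self.targets:
            if t.time_h <= self.anchor.time_h:
                raise ValueError("prediction time at or before the anchor")


@dataclass
class IndividualEstimate:
    """Empirical Bayes estimates for one patient."""

    eta: dict[str, float]
    kappa: dict[int, float] = field(default_factory=dict)
    ofv: float = np.nan
    converged: bool = False

    def eta_vector(self, model: PopPKModel) -> np.ndarray:
        return np.array([self.eta.get(name, 0.0) for name in model.eta_names])


# -- covariate and parameter trajectories ------------------------------------

def covariate_segments(model: PopPKModel, table: EventTable, pid,
                       policy: str = "locf_at_anchor",
                       anchor_h: float | None = None) -> list[tuple[float, dict]]:
    """Piecewise-constant covariate values for one patient.

    Breakpoints sit at the covariate measurement times; under
    ``locf_at_anchor`` measurements after the anchor are ignored, freezing
    every covariate (including derived ADA positivity) at its anchor value.
    """
    if policy == "locf_at_anchor" and anchor_h is None:
        raise ValueError("locf_at_anchor policy requires an anchor time")
    needed = model.required_covariates()
    p = table.patient(pid)
    times = {0.0}
    for cov in needed:
        col = "ADA" if cov == "ADA_POS" else cov
        if col in p.columns:
            rows = p[p[col].notna() & p["TIME"].notna()]
            times.update(float(t) for t in rows["TIME"])
    if policy == "locf_at_anchor":
        times = {t for t in times if t <= anchor_h}
    segs = []
    for t in sorted(times):
        vals: dict = {"TIME": t}
        for cov in needed:
            try:
                vals[cov] = table.covariate_value_at(pid, cov, t, policy=policy,
                                                     anchor=anchor_h)
            except ValueError:
                if t == 0.0 and cov != "ADA_POS":
                    # measured later: backfill the first observed value
                    vals[cov] = table.covariate_value_at(
                        pid, cov, float(p["TIME"].max()), policy="full")
                else:
                    raise
        segs.append((t, vals))
    return segs


def individual_trajectory(model: PopPKModel,
                          cov_segments: Sequence[tuple[float, Mapping]],
                          dose_times: Sequence[float],
                          eta, kappa_by_occasion: Mapping[int, float] | None = None
                          ) -> list[tuple[float, dict]]:
    """Individual parameter segments after applying covariates, η and κ.

    Occasions are dosing-interval indices; a segment boundary is placed at
    every covariate breakpoint and, when any κ is non-trivial, at every dose
    time so the occasion-specific clearance shift applies only within its
    occasion.
    """
    kappa_by_occasion = kappa_by_occasion or {}
    dose_times = np.sort(np.asarray(dose_times, float))
    breaks = {float(s) for s, _ in cov_segments}
    if kappa_by_occasion:
        breaks.update(float(t) for t in dose_times)
    starts = np.array([s for s, _ in cov_segments])
    traj = []
    for t in sorted(breaks):
        i = max(int(np.searchsorted(starts, t, side="right")) - 1, 0)
        cov = dict(cov_segments[i][1])
        cov["TIME"] = t
        occ = int(np.searchsorted(dose_times, t, side="right")) - 1
        kappa = kappa_by_occasion.get(occ, 0.0)
        traj.append((t, individual_parameters(model, cov, eta, kappa)))
    return traj


# -- MAP objective and estimation --------------------------------------------

def map_objective(model: PopPKModel, observations: Sequence[Observation],
                  doses: Sequence[DosingEvent],
                  cov_segments: Sequence[tuple[float, Mapping]],
                  eta, kappa_by_occasion: Mapping[int, float] | None = None) -> float:
    """Evaluate the MAP objective; see the module docstring for the formula."""
    omega = model.random.omega()
    eta_v = np.atleast_1d(np.asarray(eta, float))
    try:
        prior = float(eta_v @ np.linalg.solve(omega, eta_v))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular IIV covariance matrix Ω") from exc
    total = prior
    kappa_by_occasion = kappa_by_occasion or {}
    if kappa_by_occasion:
        if not model.has_iov:
            raise ValueError("κ supplied for a model without IOV")
        total += float(sum(k ** 2 for k in kappa_by_occasion.values())) / model.random.iov_cl
    if observations:
        dose_times = [d.time_h for d in doses]
        traj = individual_trajectory(model, cov_segments, dose_times, eta_v,
                                     kappa_by_occasion)
        t_obs = [o.time_h for o in observations]
        y_obs = np.array([o.conc for o in observations])
        f = concentration_profile(doses, traj, t_obs, model.n_compartments)
        g2 = model.error.variance(f)
        total += float(np.sum((y_obs - f) ** 2 / g2 + np.log(g2)))
    return total


def fit_random_effects(model: PopPKModel, observations: Sequence[Observation],
                       doses: Sequence[DosingEvent],
                       cov_segments: Sequence[tuple[float, Mapping]],
                       kappa_occasions: Sequence[int] = (),
                       seed: int = 0, n_starts: int = 5,
                       tol: float = 1e-8) -> IndividualEstimate:
    """Minimize the MAP objective over (η, κ) by multi-start local search.

    Starts at the prior mode (all zeros) plus ``n_starts − 1`` perturbed
    points drawn from the prior (fixed substream of ``seed``); the reported
    estimate never has a larger objective than the prior mode.
    """
    names = model.eta_names
    n_eta = len(names)
    occs = list(kappa_occasions) if model.has_iov else []
    dim = n_eta + len(occs)

    def unpack(x):
        return x[:n_eta], {occ: x[n_eta + i] for i, occ in enumerate(occs)}

    def objective(x):
        eta, kappas = unpack(x)
        return map_objective(model, observations, doses, cov_segments, eta, kappas)

    rng = substream(seed, "map-multistart")
    omega = model.random.omega()
    starts = [np.zeros(dim)]
    for _ in range(max(n_starts - 1, 0)):
        x0 = np.zeros(dim)
        x0[:n_eta] = rng.multivariate_normal(np.zeros(n_eta), omega)
        if occs:
            x0[n_eta:] = rng.normal(0.0, np.sqrt(model.random.iov_cl), size=len(occs))
        starts.append(0.7 * x0)

    best_x = np.zeros(dim)
    best_f = objective(best_x)
    converged = False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500})
        converged = converged or bool(res.success)
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    eta, kappas = unpack(best_x)
    return IndividualEstimate(eta=dict(zip(names, map(float, eta))),
                              kappa={k: float(v) for k, v in kappas.items()},
                              ofv=float(best_f), converged=converged)


def estimate_ebes(model: PopPKModel, task: ForecastTask,
                  seed: int = 0, n_starts: int = 5) -> IndividualEstimate:
    """EBEs from the anchor concentration, with IOV on the anchor occasion."""
    segs = covariate_segments(model, task.table, task.patient_id,
                              policy=task.policy, anchor_h=task.anchor.time_h)
    return fit_random_effects(model, [task.anchor], task.doses, segs,
                              kappa_occasions=[task.anchor.occasion] if model.has_iov else [],
                              seed=seed, n_starts=n_starts)


# -- forecasting -------------------------------------------------------------

def forecast(model: PopPKModel, est: IndividualEstimate,
             task: ForecastTask) -> list[PredictionRecord]:
    """Predict the target concentrations from the EBEs with κ ≡ 0.

    Returns one record per target plus a leading record for the anchor
    itself (its individual prediction, κ of the anchor occasion included, as
    estimated), flagged ``anchor=True`` so evaluation can exclude it.
    """
    if not est.converged:
        log.warning("forecasting patient %s from a non-converged estimate",
                    task.patient_id)
    table, pid = task.table, task.patient_id
    segs = covariate_segments(model, table, pid, policy=task.policy,
                              anchor_h=task.anchor.time_h)
    dose_times = [d.time_h for d in task.doses]
    eta_v = est.eta_vector(model)

    records = []
    traj_fit = individual_trajectory(model, segs, dose_times, eta_v, est.kappa)
    y_anchor = float(concentration_profile(task.doses, traj_fit,
                                           [task.anchor.time_h],
                                           model.n_compartments)[..., 0])
    first_ada_h = table.first_ada_time(pid)
    common = dict(
        patient_id=pid,
        ada_patient=table.ada_patient_positive(pid),
        first_ada_days=None if first_ada_h is None else first_ada_h / 24.0,
    )
    records.append(PredictionRecord(
        time_days=task.anchor.time_h / 24.0, x=task.anchor.conc, y=y_anchor,
        dt_anchor_days=0.0, ada_sample=table.ada_sample_positive(pid, task.anchor.time_h),
        trough=table.is_trough(pid, task.anchor.time_h), anchor=True, **common))

    if task.targets:
        traj_pred = individual_trajectory(model, segs, dose_times, eta_v, None)
        t_pred = [o.time_h for o in task.targets]
        y_pred = concentration_profile(task.doses, traj_pred, t_pred,
                                       model.n_compartments)
        for obs, y in zip(task.targets, np.atleast_1d(y_pred)):
            records.append(PredictionRecord(
                time_days=obs.time_h / 24.0, x=obs.conc, y=float(y),
                dt_anchor_days=(obs.time_h - task.anchor.time_h) / 24.0,
                ada_sample=table.ada_sample_positive(pid, obs.time_h),
                trough=table.is_trough(pid, obs.time_h), anchor=False, **common))
    return records


def make_forecast_task(table: EventTable, pid,
                       policy: str = "locf_at_anchor") -> Optional[ForecastTask]:
    """Build the forecasting problem for one patient of a cleaned dataset.

    Returns None for patients without any retained observation.
    """
    obs = table.observations(pid)
    if obs.empty:
        return None
    doses = [DosingEvent(float(r["TIME"]), float(r["AMT"]),
                         float(r["DUR"]) if np.isfinite(r["DUR"]) else 2.0)
             for _, r in table.doses(pid).iterrows()]
    events = []
    for _, r in obs.iterrows():
        t = float(r["TIME"])
        events.append(Observation(t, float(r["DV"]), table.occasion_of(pid, t)))
    return ForecastTask(patient_id=pid, doses=doses, anchor=events[0],
                        targets=events[1:], table=table, policy=policy)
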