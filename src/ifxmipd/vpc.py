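"""Prediction- and variability-corrected visual predictive checks (pvcVPC).

A VPC simulates the study population many times under the model (fresh
inter-individual, inter-occasion and residual draws at the real dosing,
covariate and sampling design) and compares percentiles of the observations
with the simulation-based distribution of those percentiles. Because dose
per kilogram and sampling times vary across patients, both observations and
simulations are first normalised within time-after-dose bins:

* prediction correction — each value is rescaled by the ratio of the bin's
  median typical prediction (PRED, all random effects zero) to that
  observation's own PRED;
* variability correction — the residual from the bin's median PRED is then
  rescaled by the ratio of the bin's median simulation SD to that
  observation's simulation SD (SD across replicates of the
  prediction-corrected simulated values).

Percentile bands (default 5th/50th/95th) of the corrected observations are
then overlaid on the simulation-based median and 95% confidence interval of
each percentile, per quantile bin of time after the most recent dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._rng import substream
from .data_io import EventTable
from .map_forecast import covariate_segments, individual_trajectory, make_forecast_task
from .model_config import PopPKModel, validate_against_dataset
from .pk_engine import concentration_profile, simulate_observation

log = logging.getLogger(__name__)

__all__ = [
    "VPCConfig",
    "VPCSimulation",
    "VPCResult",
    "simulate_replicates",
    "pvc_transform",
    "pvc_correct",
    "vpc_summary",
    "run_vpc",
]


@dataclass(frozen=True)
class VPCConfig:
    n_replicates: int = 1000
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    ci_level: float = 95.0
    n_bins: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(not 0 < p < 100 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")


@dataclass
class VPCSimulation:
    """Replicated observations plus typical predictions at the study design."""

    obs: np.ndarray          # (n_obs,) observed concentrations
    pred: np.ndarray         # (n_obs,) typical predictions (η = κ = ε = 0)
    sims: np.ndarray         # (n_replicates, n_obs) simulated observations
    tad_h: np.ndarray        # (n_obs,) time after most recent dose
    patient_ids: np.ndarray  # (n_obs,)


@dataclass
class VPCResult:
    """Binned percentile summary of a pvcVPC."""

    bin_edges: np.ndarray
    bins: list[dict] = field(default_factory=list)
    # each bin: {tad_mid_h, n, obs: {pct: value}, sim: {pct: {median, lo, hi}}}

    def median_coverage(self) -> float:
        """Fraction of bins whose observed median lies inside the simulated
        95% CI of the median — the basic self-consistency diagnostic."""
        inside = [b["sim"][50.0]["lo"] <= b["obs"][50.0] <= b["sim"][50.0]["hi"]
                  for b in self.bins]
        return float(np.mean(inside)) if inside else np.nan

    def to_dict(self) -> dict:
        return {"bin_edges_h": self.bin_edges.tolist(),
                "bins": [{**b, "obs": {str(k): v for k, v in b["obs"].items()},
                          "sim": {str(k): v for k, v in b["sim"].items()}}
                         for b in self.bins]}


def simulate_replicates(model: PopPKModel, data: EventTable,
                        cfg: VPCConfig | None = None) -> VPCSimulation:
    """Simulate ``n_replicates`` of the study population under the model.

    Each replicate redraws η per patient, κ per dosing occasion and residual
    error per sample, while keeping every patient's dosing history,
    covariate time course and sampling times fixed. The typical prediction
    PRED (all random effects zero) is computed once per observation.
    """
    cfg = cfg or VPCConfig()
    findings = validate_against_dataset(model, data)
    if findings:
        raise ValueError("model/dataset incompatibility: " + "; ".join(findings))
    rng_eta = substream(cfg.seed, "vpc-eta")
    rng_eps = substream(cfg.seed, "vpc-eps")
    R = cfg.n_replicates
    omega = model.random.omega()

    obs_all, pred_all, sims_all, tad_all, pid_all = [], [], [], [], []
    for pid in data.patients():
        task = make_forecast_task(data, pid, policy="full")
        if task is None:
            continue
        obs = [task.anchor] + task.targets
        t_obs = np.array([o.time_h for o in obs])
        segs = covariate_segments(model, data, pid, policy="full")
        dose_times = np.sort(np.array([d.time_h for d in task.doses]))

        eta = rng_eta.multivariate_normal(np.zeros(len(model.eta_names)), omega, size=R)
        eta_b = {name: eta[:, i] for i, name in enumerate(model.eta_names)}
        kappas = None
        if model.has_iov:
            occs = sorted({o.occasion for o in obs})
            kappas = {occ: rng_eta.normal(0.0, np.sqrt(model.random.iov_cl), size=R)
                      for occ in occs}
        traj = individual_trajectory(model, segs, dose_times, eta_b, kappas)
        f = concentration_profile(task.doses, traj, t_obs, model.n_compartments)
        sims = simulate_observation(f, model.error, rng_eps)

        traj0 = individual_trajectory(model, segs, dose_times, None, None)
        pred = concentration_profile(task.doses, traj0, t_obs, model.n_compartments)

        last_dose = dose_times[np.searchsorted(dose_times, t_obs, side="right") - 1]
        obs_all.append(np.array([o.conc for o in obs]))
        pred_all.append(np.atleast_1d(pred))
        sims_all.append(sims)
        tad_all.append(t_obs - last_dose)
        pid_all.extend([pid] * len(obs))

    return VPCSimulation(obs=np.concatenate(obs_all),
                         pred=np.concatenate(pred_all),
                         sims=np.concatenate(sims_all, axis=1),
                         tad_h=np.concatenate(tad_all),
                         patient_ids=np.asarray(pid_all))


def pvc_transform(value, pred_ij, bin_pred_median, sd_ij, bin_sd_median):
    """Prediction- then variability-correct one value (or array of replicates).

    Falls back to the prediction correction alone when the local simulation
    SD is zero (degenerate, e.g. a variance-free model).
    """
    if pred_ij <= 0:
        raise ValueError("typical prediction must be > 0 for correction")
    pc = np.asarray(value, float) * (bin_pred_median / pred_ij)
    if sd_ij <= 0:
        if np.any(pc != bin_pred_median):
            log.warning("zero simulation SD with nonzero residual; "
                        "prediction correction only")
        return pc
    return bin_pred_median + (pc - bin_pred_median) * (bin_sd_median / sd_ij)


def _quantile_bins(tad: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(tad, qs))
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    # merge bins with fewer than 2 observations into their left neighbour
    while len(edges) > 2:
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.flatnonzero(counts < 2)
        if small.size == 0:
            break
        k = int(small[0])
        edges = np.delete(edges, max(k, 1))
        log.warning("merged VPC bin %d with its neighbour (fewer than 2 observations)", k)
        idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    return edges, idx


def pvc_correct(sim: VPCSimulation, cfg: VPCConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply the pvc transform to observations and simulations.

    Returns (corrected obs, corrected sims, bin index per obs, bin edges).
    """
    cfg = cfg or VPCConfig()
    edges, idx = _quantile_bins(sim.tad_h, cfg.n_bins)
    n_obs = sim.obs.size
    obs_c = np.empty(n_obs)
    sims_c = np.empty_like(sim.sims)

    pc_sims = sim.sims * (1.0 / sim.pred)  # partial: per-obs scaling applied below
    for b in range(len(edges) - 1):
        mask = idx == b
        bin_pred_med = float(np.median(sim.pred[mask]))
        # SD across replicates of the prediction-corrected simulations
        sd = np.std(pc_sims[:, mask] * bin_pred_med, axis=0, ddof=1)
        bin_sd_med = float(np.median(sd))
        for local_j, j in enumerate(np.flatnonzero(mask)):
            obs_c[j] = pvc_transform(sim.obs[j], sim.pred[j], bin_pred_med,
                                     sd[local_j], bin_sd_med)
            sims_c[:, j] = pvc_transform(sim.sims[:, j], sim.pred[j], bin_pred_med,
                                         sd[local_j], bin_sd_med)
    return obs_c, sims_c, idx, edges


def vpc_summary(obs_c: np.ndarray, sims_c: np.ndarray, idx: np.ndarray,
                edges: np.ndarray, tad_h: np.ndarray,
                cfg: VPCConfig | None = None) -> VPCResult:
    """Percentile summary per bin: observed vs simulation distribution."""
    cfg = cfg or VPCConfig()
    alpha = (100.0 - cfg.ci_level) / 2.0
    result = VPCResult(bin_edges=edges)
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        entry = {"tad_mid_h": float(np.median(tad_h[mask])), "n": int(mask.sum()),
                 "obs": {}, "sim": {}}
        for p in cfg.percentiles:
            entry["obs"][p] = float(np.percentile(obs_c[mask], p))
            # distribution of this percentile across replicates
            rep_pct = np.percentile(sims_c[:, mask], p, axis=1)
            entry["sim"][p] = {"median": float(np.median(rep_pct)),
                               "lo": float(np.percentile(rep_pct, alpha)),
                               "hi": float(np.percentile(rep_pct, 100.0 - alpha))}
        result.bins.append(entry)
    return result


def run_vpc(model: PopPKModel, data: EventTable,
            cfg: VPCConfig | None = None) -> VPCResult:
    """Simulate, correct and summarise in one call."""
    cfg = cfg or VPCConfig()
    sim = simulate_replicates(model, data, cfg)
    obs_c, sims_c, idx, edges = pvc_correct(sim, cfg)
    return vpc_summary(obs_c, sims_c, idx, edges, sim.tad_h, cfg)


def plot_vpc(result: VPCResult, path=None, ax=None):
    """Band plot of a pvcVPC summary (percentile lines + CI bands)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    t = [b["tad_mid_h"] / 24.0 for b in result.bins]
    for p, color in zip(sorted({p for b in result.bins for p in b["obs"]}),
                        ("tab:blue", "black", "tab:blue")):
        obs = [b["obs"][p] for b in result.bins]
        med = [b["sim"][p]["median"] for b in result.bins]
        lo = [b["sim"][p]["lo"] for b in result.bins]
        hi = [b["sim"][p]["hi"] for b in result.bins]
        ax.fill_between(t, lo, hi, alpha=0.25, color=color)
        ax.plot(t, med, color=color, ls="--", lw=1)
        ax.plot(t, obs, color=color, lw=1.5)
    ax.set_xlabel("time after dose [days]")
    ax.set_ylabel("corrected concentration [µg/mL]")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
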