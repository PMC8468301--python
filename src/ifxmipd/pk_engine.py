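"""Exact concentration prediction for IV-infusion compartment models.

Linear 1- and 2-compartment models with zero-order infusion input admit
closed-form solutions within any time span where the individual parameters
and the total infusion rate are constant. The engine therefore splits time at
dose starts/stops and parameter breakpoints (covariate changes, occasion
switches) and propagates the compartment *amounts* exactly across each
segment with the analytic matrix exponential of the 2×2 disposition matrix
(scalar exponential for one compartment). Amounts in both compartments are
carried across breakpoints, so piecewise-varying parameters are handled
without any ODE integration.

All parameter values may be numpy arrays of a common broadcast shape, in
which case profiles for the whole batch (e.g. all VPC replicates of one
patient) are computed in a single vectorized pass.

Units: hours, mg, L — central-compartment concentration is mg/L ≡ µg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_config import PopPKModel, ResidualErrorSpec

__all__ = [
    "DosingEvent",
    "individual_parameters",
    "concentration_profile",
    "simulate_observation",
]


@dataclass(frozen=True)
class DosingEvent:
    """One zero-order IV infusion."""

    time_h: float
    amount_mg: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be > 0")
        if self.duration_h <= 0:
            raise ValueError("infusion duration must be > 0")


def _covariate_multiplier(eff, covariates: Mapping, defaults: Mapping) -> float | np.ndarray:
    if eff.form == "piecewise_time_multiplier":
        t = covariates.get("TIME", 0.0)
        return np.where(np.asarray(t) >= eff.onset_h, eff.coefficient, 1.0)
    if eff.covariate in covariates:
        v = covariates[eff.covariate]
    elif eff.covariate in defaults:
        v = defaults[eff.covariate]
    else:
        raise KeyError(f"missing covariate {eff.covariate!r}")
    if v is None or (np.isscalar(v) and isinstance(v, float) and np.isnan(v)):
        raise KeyError(f"missing covariate {eff.covariate!r}")
    v = np.asarray(v, float)
    if eff.form == "power":
        return (v / eff.reference) ** eff.coefficient
    if eff.form == "proportional":
        return 1.0 + eff.coefficient * (v - eff.reference)
    if eff.form == "exponential":
        return np.exp(eff.coefficient * (v - eff.reference))
    if eff.form == "binary_multiplier":
        return np.where(v != 0, eff.coefficient, 1.0)
    raise ValueError(f"unknown covariate form {eff.form!r}")  # pragma: no cover


def individual_parameters(model: PopPKModel, covariates: Mapping,
                          eta: Mapping | Sequence | None = None,
                          kappa: float | np.ndarray = 0.0) -> dict:
    """Individual structural parameters, in hour units.

    ``P_i = P_pop · Π multipliers · exp(η_P)``, with ``exp(κ)`` applied to CL
    in addition when inter-occasion variability is active. ``eta`` is either
    a mapping parameter→value or a sequence in ``model.eta_names`` order;
    entries may be arrays for batched evaluation.
    """
    params = {k: np.asarray(v, float) for k, v in model.typical_hour_units().items()}
    for eff in model.covariate_effects:
        params[eff.target] = params[eff.target] * _covariate_multiplier(
            eff, covariates, model.covariate_defaults)
    if eta is not None:
        if not isinstance(eta, Mapping):
            eta = dict(zip(model.eta_names, eta))
        for name, val in eta.items():
            if name not in params:
                raise KeyError(f"η on unknown parameter {name!r}")
            params[name] = params[name] * np.exp(np.asarray(val, float))
    params["CL"] = params["CL"] * np.exp(np.asarray(kappa, float))
    for name, val in params.items():
        if np.any(val <= 0):
            raise ValueError(f"non-positive individual parameter {name}")
    return params


# -- analytic propagation ----------------------------------------------------

def _step_1cmt(A1, p, rate, tau):
    k10 = p["CL"] / p["Vc"]
    ss = rate / k10
    return ss + (A1 - ss) * np.exp(-k10 * tau)


def _step_2cmt(A1, A2, p, rate, tau):
    CL, Vc, Q, Vp = p["CL"], p["Vc"], p["Q"], p["Vp"]
    k10, k12, k21 = CL / Vc, Q / Vc, Q / Vp
    m11, m12, m21, m22 = -(k10 + k12), k21, k12, -k21
    tr = m11 + m22
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * k10 * k21, 0.0))
    # repeated eigenvalues occur only on a measure-zero parameter set; nudge
    disc = np.maximum(disc, 1e-12 * np.abs(tr))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    e1, e2 = np.exp(l1 * tau), np.exp(l2 * tau)
    dl = l1 - l2
    p11 = (e1 * (m11 - l2) - e2 * (m11 - l1)) / dl
    p12 = m12 * (e1 - e2) / dl
    p21 = m21 * (e1 - e2) / dl
    p22 = (e1 * (m22 - l2) - e2 * (m22 - l1)) / dl
    ss1 = rate / k10
    ss2 = rate * Vp / CL  # = rate·k12/(k10·k21)
    x1, x2 = A1 - ss1, A2 - ss2
    return ss1 + p11 * x1 + p12 * x2, ss2 + p21 * x1 + p22 * x2


def concentration_profile(doses: Sequence[DosingEvent],
                          trajectory: Sequence[tuple[float, Mapping]],
                          times, n_compartments: int = 2) -> np.ndarray:
    """Central-compartment concentrations at the requested times.

    ``trajectory`` is a sorted list of ``(start_h, params)`` segments; the
    first segment must start at or before 0 and parameters apply from their
    segment start until the next. Parameter values may be arrays of a common
    broadcast shape ``B``; the result then has shape ``B + (len(times),)``.
    """
    times = np.atleast_1d(np.asarray(times, float))
    if times.size and times.min() < 0:
        raise ValueError("prediction time before 0")
    if not trajectory:
        raise ValueError("empty parameter trajectory")
    if trajectory[0][0] > 0:
        raise ValueError("trajectory must cover t = 0")

    shapes = [np.shape(v) for _, p in trajectory for v in p.values()]
    batch = np.broadcast_shapes(*shapes) if shapes else ()

    if not doses:
        return np.zeros(batch + (times.size,))

    events = {0.0}
    for d in doses:
        events.add(float(d.time_h))
        events.add(float(d.time_h + d.duration_h))
    for start, _ in trajectory:
        if start > 0:
            events.add(float(start))
    grid = np.unique(np.concatenate([np.array(sorted(events)), times]))
    grid = grid[grid >= 0]

    seg_starts = np.array([s for s, _ in trajectory], float)

    def params_at(t: float) -> Mapping:
        i = int(np.searchsorted(seg_starts, t, side="right")) - 1
        return trajectory[max(i, 0)][1]

    A1 = np.zeros(batch)
    A2 = np.zeros(batch)
    conc_at = {}
    t_prev = float(grid[0])
    conc_at[t_prev] = A1 / np.asarray(params_at(t_prev)["Vc"], float)
    for t in grid[1:]:
        t = float(t)
        mid = 0.5 * (t_prev + t)
        p = params_at(mid)
        rate = sum(d.amount_mg / d.duration_h for d in doses
                   if d.time_h <= mid < d.time_h + d.duration_h)
        if n_compartments == 2:
            A1, A2 = _step_2cmt(A1, A2, p, rate, t - t_prev)
        else:
            A1 = _step_1cmt(A1, p, rate, t - t_prev)
        conc_at[t] = A1 / np.asarray(params_at(t)["Vc"], float)
        t_prev = t

    out = np.empty(batch + (times.size,))
    for j, t in enumerate(times):
        out[..., j] = conc_at[float(t)]
    return out


def simulate_observation(profile_value, error: ResidualErrorSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw observed concentrations: y = f·(1+ε_p) + ε_a, truncated at 0."""
    f = np.asarray(profile_value, float)
    if np.any(f < 0):
        raise ValueError("negative model prediction")
    y = f
    if error.sigma_prop > 0:
        y = y * (1.0 + rng.normal(0.0, error.sigma_prop, size=f.shape))
    if error.sigma_add > 0:
        y = y + rng.normal(0.0, error.sigma_add, size=f.shape)
    return np.maximum(np.asarray(y, float), 0.0)
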