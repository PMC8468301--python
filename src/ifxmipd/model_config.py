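"""Declarative population-PK model definitions.

A model file (YAML or JSON) declares the structural model (1 or 2 disposition
compartments, IV infusion input), typical parameter values, covariate effects
on CL/Vc/Q/Vp, log-normal inter-individual variability (IIV, η), optional
inter-occasion variability on clearance (IOV, κ, one occasion per dosing
interval), and a combined proportional + additive residual-error model.

Typical values may be declared per day (the conventional reporting unit for
monoclonal antibodies) and are converted to hours on load; everything
downstream works in hours, litres, mg and µg/mL.

Random effects enter multiplicatively: ``P_i = P_pop · Π(covariate
multipliers) · exp(η_P)``, with an extra ``exp(κ)`` on CL for the current
occasion when IOV is active.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "StructuralParameters",
    "CovariateEffect",
    "RandomEffectSpec",
    "ResidualErrorSpec",
    "PopPKModel",
    "load_model_spec",
    "serialize_model",
    "validate_against_dataset",
    "reference_model",
    "packaged_model_path",
]

SCHEMA_VERSION = 1

PARAM_NAMES = ("CL", "Vc", "Q", "Vp")


class StructuralParameters(BaseModel):
    """Typical (population) disposition parameters, in L and L/day."""

    model_config = ConfigDict(extra="forbid")

    CL: float = Field(gt=0, description="clearance, L/day")
    Vc: float = Field(gt=0, description="central volume, L")
    Q: Optional[float] = Field(default=None, gt=0, description="intercompartmental clearance, L/day")
    Vp: Optional[float] = Field(default=None, gt=0, description="peripheral volume, L")


class CovariateEffect(BaseModel):
    """One multiplicative covariate effect on a structural parameter.

    Forms
    -----
    power
        ``(cov / reference) ** coefficient`` (e.g. allometric weight scaling).
    proportional
        ``1 + coefficient · (cov − reference)``.
    exponential
        ``exp(coefficient · (cov − reference))``.
    binary_multiplier
        ``coefficient`` when the (boolean) covariate is truthy, else 1
        (the usual handling of ADA positivity on CL).
    piecewise_time_multiplier
        ``coefficient`` from ``onset_h`` hours after the first dose onward,
        else 1 (approximates published time-varying-clearance components).
    """

    model_config = ConfigDict(extra="forbid")

    target: Literal["CL", "Vc", "Q", "Vp"]
    covariate: str
    form: Literal["power", "proportional", "exponential",
                  "binary_multiplier", "piecewise_time_multiplier"]
    coefficient: float
    reference: Optional[float] = None
    onset_h: Optional[float] = None

    @model_validator(mode="after")
    def _check_form(self) -> "CovariateEffect":
        if self.form == "power":
            if self.reference is None or self.reference <= 0:
                raise ValueError("power form requires a positive reference value")
        if self.form in ("proportional", "exponential") and self.reference is None:
            object.__setattr__(self, "reference", 0.0)
        if self.form == "piecewise_time_multiplier" and self.onset_h is None:
            raise ValueError("piecewise_time_multiplier requires onset_h")
        if self.form == "binary_multiplier" and self.coefficient <= 0:
            raise ValueError("binary multiplier must be a positive fold-change")
        return self


class RandomEffectSpec(BaseModel):
    """IIV covariance (log scale) and optional IOV variance on CL."""

    model_config = ConfigDict(extra="forbid")

    iiv: dict[str, float] = Field(description="per-parameter η variance (ω²), log scale")
    iiv_corr: Optional[list[list[float]]] = Field(
        default=None, description="correlation matrix in the key order of `iiv`")
    iov_cl: Optional[float] = Field(default=None, ge=0, description="κ variance (π²) on CL")

    @model_validator(mode="after")
    def _check(self) -> "RandomEffectSpec":
        if not self.iiv:
            raise ValueError("at least one IIV term is required")
        for k, v in self.iiv.items():
            if k not in PARAM_NAMES:
                raise ValueError(f"unknown IIV parameter {k!r}")
            if v < 0:
                raise ValueError(f"negative variance for η_{k}")
        if self.iiv_corr is not None:
            n = len(self.iiv)
            m = np.asarray(self.iiv_corr, float)
            if m.shape != (n, n):
                raise ValueError("iiv_corr shape must match the number of IIV terms")
            if not np.allclose(m, m.T):
                raise ValueError("iiv_corr must be symmetric")
        omega = self.omega()
        eig = np.linalg.eigvalsh(omega)
        if eig.min() < -1e-10:
            raise ValueError("Ω must be positive semidefinite")
        return self

    @property
    def eta_names(self) -> list[str]:
        return list(self.iiv.keys())

    def omega(self) -> np.ndarray:
        """Assemble the IIV covariance matrix Ω."""
        sd = np.sqrt(np.asarray(list(self.iiv.values()), float))
        corr = (np.asarray(self.iiv_corr, float) if self.iiv_corr is not None
                else np.eye(len(sd)))
        return corr * np.outer(sd, sd)


class ResidualErrorSpec(BaseModel):
    """Combined residual error: y = f·(1 + ε_p) + ε_a."""

    model_config = ConfigDict(extra="forbid")

    sigma_prop: float = Field(default=0.0, ge=0, description="proportional SD")
    sigma_add: float = Field(default=0.0, ge=0, description="additive SD, µg/mL")

    @model_validator(mode="after")
    def _check(self) -> "ResidualErrorSpec":
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("at least one of sigma_prop, sigma_add must be > 0")
        return self

    def variance(self, f):
        """g² = σ_add² + σ_prop²·f², evaluated at prediction f."""
        return self.sigma_add ** 2 + (self.sigma_prop * np.asarray(f)) ** 2


class PopPKModel(BaseModel):
    """A complete population-PK model definition (one published-model row)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    name: str
    n_compartments: Literal[1, 2]
    time_unit: Literal["day", "hour"] = "day"
    typical: StructuralParameters
    covariate_effects: list[CovariateEffect] = Field(default_factory=list)
    random: RandomEffectSpec
    error: ResidualErrorSpec
    covariate_defaults: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PopPKModel":
        two = self.n_compartments == 2
        has_peripheral = self.typical.Q is not None or self.typical.Vp is not None
        if two and (self.typical.Q is None or self.typical.Vp is None):
            raise ValueError("2-compartment model requires Q and Vp")
        if not two and has_peripheral:
            raise ValueError("1-compartment model must not declare Q or Vp")
        for eff in self.covariate_effects:
            if eff.target in ("Q", "Vp") and not two:
                raise ValueError(f"covariate effect on {eff.target} in a 1-CMT model")
        for p in self.random.iiv:
            if p in ("Q", "Vp") and not two:
                raise ValueError(f"IIV on {p} in a 1-CMT model")
        return self

    # -- conveniences --------------------------------------------------------

    @property
    def eta_names(self) -> list[str]:
        return self.random.eta_names

    @property
    def has_iov(self) -> bool:
        return bool(self.random.iov_cl)

    def required_covariates(self) -> list[str]:
        """Dataset covariates the model needs (time is not a dataset column)."""
        out = []
        for eff in self.covariate_effects:
            if eff.form == "piecewise_time_multiplier":
                continue
            if eff.covariate not in out and eff.covariate not in self.covariate_defaults:
                out.append(eff.covariate)
        return out

    def typical_hour_units(self) -> dict[str, float]:
        """Typical values with clearances converted to L/h."""
        scale = 1.0 / 24.0 if self.time_unit == "day" else 1.0
        d = {"CL": self.typical.CL * scale, "Vc": self.typical.Vc}
        if self.n_compartments == 2:
            d["Q"] = self.typical.Q * scale
            d["Vp"] = self.typical.Vp
        return d

    def to_dict(self) -> dict:
        return self.model_dump(exclude_none=True)


# -- loading / serialization -------------------------------------------------

def load_model_spec(path: str | Path) -> PopPKModel:
    """Load and fully validate a model definition from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: model file must contain a mapping")
    if _has_placeholders(raw):
        raise ValueError(
            f"{path}: contains null parameter placeholders — transcribe values "
            "from the original publication before use")
    return PopPKModel.model_validate(raw)


def _has_placeholders(raw: dict) -> bool:
    typical = raw.get("typical")
    return isinstance(typical, dict) and any(v is None for v in typical.values())


def serialize_model(model: PopPKModel, path: str | Path) -> None:
    path = Path(path)
    data = model.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def validate_against_dataset(model: PopPKModel, data) -> list[str]:
    """Findings for covariates the model needs but the dataset lacks.

    An empty list means the model is compatible. ``ADA_POS`` resolves against
    the ADA measurement column; other covariates must exist as columns with at
    least one non-missing value.
    """
    findings = []
    df = data.df
    for cov in model.required_covariates():
        col = "ADA" if cov == "ADA_POS" else cov
        if col not in df.columns or df[col].notna().sum() == 0:
            findings.append(f"covariate {cov!r} required by model {model.name!r} "
                            "is absent from the dataset")
    return findings


# -- packaged model definitions ---------------------------------------------

def packaged_model_path(name: str) -> Path:
    """Path of a model definition shipped with the package."""
    p = Path(__file__).parent / "models" / f"{name}.yaml"
    if not p.exists():
        available = sorted(q.stem for q in p.parent.glob("*.yaml"))
        raise FileNotFoundError(f"no packaged model {name!r}; available: {available}")
    return p


def reference_model() -> PopPKModel:
    """The fully parameterized reference model used throughout the test suite.

    A generic 2-compartment monoclonal-antibody model with allometric weight
    scaling, a binary ADA clearance multiplier, IIV on CL and Vc, IOV on CL
    and combined residual error. Parameter values are plausible for
    infliximab but are a package-defined construct, not transcribed from any
    published model.
    """
    return load_model_spec(packaged_model_path("reference"))
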