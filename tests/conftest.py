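import numpy as np
import pandas as pd
import pytest

from ifxmipd.data_io import EventTable, apply_exclusion_cascade
from ifxmipd.model_config import PopPKModel, reference_model
from ifxmipd.synthetic_cohort import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def ref_model() -> PopPKModel:
    return reference_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient virtual cohort, cleaned, shared across tests."""
    table, truth = generate_cohort(SyntheticCohortConfig(n_patients=40), seed=7)
    clean, _ = apply_exclusion_cascade(table)
    return clean, truth


def toy_1cmt(sigma_prop=0.1, sigma_add=0.0, omega_cl=0.09, omega_vc=None,
             iov=None):
    """A covariate-free 1-compartment model for analytic checks."""
    iiv = {"CL": omega_cl}
    if omega_vc is not None:
        iiv["Vc"] = omega_vc
    return PopPKModel.model_validate({
        "name": "toy",
        "n_compartments": 1,
        "time_unit": "day",
        "typical": {"CL": 0.3, "Vc": 3.5},
        "random": {"iiv": iiv, **({"iov_cl": iov} if iov else {})},
        "error": {"sigma_prop": sigma_prop, "sigma_add": sigma_add},
    })


@pytest.fixture
def toy_model():
    return toy_1cmt()


def single_patient_table(obs, doses=((0.0, 385.0, 2.0),), covs=None,
                         ada=None, pid="P1"):
    """Build a one-patient EventTable from (time_h, conc) observation pairs."""
    covs = covs or {"WT": 70.0, "ALB": 4.35}
    rows = []
    for t, amt, dur in doses:
        rows.append({"ID": pid, "TIME": t, "EVID": 1, "AMT": amt, "DUR": dur,
                     "DV": np.nan, "MDV": 1, "BLQ": False,
                     "ADA": np.nan, **covs})
    for i, (t, dv) in enumerate(obs):
        a = np.nan if ada is None else ada[i]
        rows.append({"ID": pid, "TIME": t, "EVID": 0, "AMT": np.nan,
                     "DUR": np.nan, "DV": dv, "MDV": 0, "BLQ": False,
                     "ADA": a, **covs})
    return EventTable(pd.DataFrame(rows))
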