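import logging

import numpy as np
import pandas as pd
import pytest

from stoolpanel.simulate import CohortDesign, generate_cohort
from stoolpanel.types import ArmCallProfile, CountMatrix, SampleTable

logging.getLogger("stoolpanel").setLevel(logging.ERROR)


@pytest.fixture()
def toy_matrix() -> CountMatrix:
    return CountMatrix(
        ["HBA1", "HP"],
        ["s1", "s2", "s3"],
        np.array([[5, 0, 7], [1, 2, 3]]),
    )


@pytest.fixture()
def toy_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "patient_id": ["p1", "p2", "p3"],
                "diagnosis_class": ["control", "high_risk_adenoma", "crc"],
                "morphology": ["not_applicable", "advanced", "not_applicable"],
                "fit_value": [1.0, np.nan, 3.0],
                "hp_value": [np.nan, 2.0, 4.0],
            }
        )
    )


def profile(adenoma_id="a1", patient_id="p1", **calls) -> ArmCallProfile:
    base = {a: "neutral" for a in ("8p", "8q", "13q", "15q", "17p", "18q", "20q")}
    base.update(calls)
    return ArmCallProfile(adenoma_id, patient_id, base)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    design = CohortDesign(
        n_controls=40, n_low_risk=12, n_high_risk=8, n_crc=15,
        n_proteins=80, n_differential_hr=5, n_differential_crc=12, seed=42,
    )
    return generate_cohort(design)
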