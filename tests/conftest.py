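import datetime as dt

import pandas as pd
import pytest

from mwascreen.claims_model import (
    ClaimsBundle,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
    TreatmentRecord,
    bundle_from_records,
)
from mwascreen.synthetic_claims import DrugSpec, SimulationConfig


@pytest.fixture
def tiny_bundle() -> ClaimsBundle:
    """Three hand-written patients: one full case, one without treatment
    evidence, one with a non-qualifying diagnosis."""
    return bundle_from_records(
        patients=[
            PatientRecord("P001", "male", 1950,
                          dt.date(2008, 6, 1), "target_cancer"),
            PatientRecord("P002", "female", 1960),
            PatientRecord("P003", "male", 1945),
        ],
        diagnoses=[
            DiagnosisRecord("P001", dt.date(2005, 2, 10), "C189"),
            DiagnosisRecord("P002", dt.date(2006, 3, 5), "C18"),
            DiagnosisRecord("P003", dt.date(2007, 1, 20), "C50"),
        ],
        treatments=[
            TreatmentRecord("P001", dt.date(2005, 3, 1), "operation"),
            TreatmentRecord("P003", dt.date(2007, 2, 1), "colonoscopy"),
        ],
        prescriptions=[
            PrescriptionRecord("P001", dt.date(2004, 12, 1), "B01AC06"),
            PrescriptionRecord("P001", dt.date(2005, 1, 15), "N07AA02"),
        ],
        coverage_start=dt.date(2002, 1, 1),
        coverage_end=dt.date(2015, 12, 31),
        anticancer_atc_prefixes=("L01", "L02"),
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A quick five-drug scenario for pipeline-level tests."""
    return SimulationConfig(
        n_patients=400,
        drugs=(
            DrugSpec("N07AA02", 0.12, 0.06, -0.7, -0.7),
            DrugSpec("A02AA04", 0.10, 0.05, 0.7, 0.7),
            DrugSpec("B01AC06", 0.10, 0.06, 0.0, 0.0),
            DrugSpec("N07AB01", 0.08, 0.04, 0.0, 0.0),
            DrugSpec("C10AA01", 0.08, 0.05, 0.0, 0.0),
        ),
        p_anticancer_rx=0.3,
        seed=11,
    )
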