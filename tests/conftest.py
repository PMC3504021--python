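import numpy as np
import pandas as pd
import pytest

from crlmsig.cohort import ClinicalRecord, records_to_frame
from crlmsig.synthdata import CohortSpec, generate_cohort


_RECORD_DEFAULTS = dict(
    patient_id="P001",
    center="A",
    sex="male",
    age=62.0,
    primary_site="colon",
    differentiation="moderate",
    primary_stage=3,
    nodal_status="negative",
    interval_to_metastasis=14.0,
    n_metastases=1,
    largest_metastasis_cm=3.0,
    distribution="unilobar",
    preop_cea=12.0,
    neoadjuvant=0,
    adjuvant=0,
    resection_extent="minor",
    margin="R0",
    hepatoduodenal_nodes="unknown",
    dfs_months=24.0,
    event=0,
)


@pytest.fixture
def make_record():
    """Factory for ClinicalRecord toys; override any field by keyword."""

    def _make(**kw) -> ClinicalRecord:
        return ClinicalRecord(**{**_RECORD_DEFAULTS, **kw})

    return _make


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a strong planted 30-gene signature."""
    spec = CohortSpec(
        n_patients=119,
        n_genes=500,
        signature_genes=30,
        signature_effect=2.0,
        treatment_effect_genes=50,
        treatment_effect_size=0.5,
        noise_sd=1.0,
        seed=5,
    )
    records, study, qc = generate_cohort(spec)
    return records, study, records_to_frame(records)
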