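import numpy as np
import pytest
from hypothesis import settings

import hemoprev as hp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_model():
    return hp.ReferenceModel()


@pytest.fixture(scope="session")
def default_refs(reference_model):
    """Reference CDFs at the modal (reference-condition) covariates."""
    clean = hp.simulate_reference_population(reference_model, None, False, 100_000, 10)
    dope = hp.simulate_reference_population(reference_model, None, True, 100_000, 11)
    return hp.build_reference_cdfs(clean, dope)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition cohort reused across read-only tests."""
    config = hp.CohortConfig(n_daegu=600, n_moscow=600, seed=42)
    return hp.generate_cohort(config)


@pytest.fixture
def reference_record():
    """A reference-condition record (male, morning, Europe, first event)."""
    hgb, hct, rbc = 15.2, 45.0, 5.0
    mcv, mch, mchc = hp.derive_indices(hgb, hct, rbc)
    return hp.AthleteRecord(
        athlete_id="ref-001",
        event="Daegu2011",
        sex="M",
        age_class="a19_24",
        age=24.0,
        country="EU-A",
        continent="Europe",
        ethnicity="Caucasian",
        endurance=True,
        altitude_class="lt1000",
        sampling_time="morning",
        HGB=hgb, HCT=hct, RBC=rbc, RET_pct=1.2,
        MCV=mcv, MCH=mch, MCHC=mchc,
    )
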