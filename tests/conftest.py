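import pytest

from airwayprot import load_study_panel
from airwayprot.synth import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    """The bundled eight-patient study panel."""
    return load_study_panel()


@pytest.fixture(scope="session")
def score_panel(panel):
    return panel.to_score_panel()


@pytest.fixture(scope="session")
def cohort():
    """One seeded synthetic cohort with the designated crossover patient."""
    cfg = SyntheticCohortConfig(seed=11, crossover_nor=True)
    profiles, records = generate_cohort(cfg)
    return profiles, records
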