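import pytest

import etrec as E


@pytest.fixture(scope="session")
def pipeline():
    """One shared default-configuration pipeline (memoises per-pair solves)."""
    return E.SimulationPipeline()


@pytest.fixture(scope="session")
def training_samples(pipeline):
    """The full 5-subject x 36-configuration PCS-labelled training set."""
    return E.build_training_set(list(E.TRAINING_COHORT), pipeline)


@pytest.fixture(scope="session")
def cohort_pcs(pipeline):
    """Computed PCS values for each test-cohort subject, enumeration order."""
    return {s.subject_id: pipeline.pcs_values(s) for s in E.EXPERIMENT_COHORT}
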