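import pytest

from mergecall import CohortConfig, run_experiment
from mergecall.cohort import build_samples


@pytest.fixture(scope="session")
def default_bundle():
    """Full experiment on the default cohort (1000 sites, 24 samples, seed 0)."""
    return run_experiment(CohortConfig())


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same cohort generated without sequencing error (called at eps=0.01)."""
    return run_experiment(CohortConfig(error_rate=0.0))


@pytest.fixture(scope="session")
def study_samples():
    """The 2-group x 2-tissue x 6-animal sample sheet."""
    return build_samples(6)
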