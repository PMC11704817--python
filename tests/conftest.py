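import pytest

from toricalc import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 80-eye synthetic cohort shared by I/O and CLI tests."""
    return generate_cohort(CohortConfig(n_eyes=80, seed=7))
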