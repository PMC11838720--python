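import pytest

from deltacheck import CohortConfig, compute_deltas, generate_cohort
from deltacheck.reference import DEFAULT_ANALYTES

CORTISOL = DEFAULT_ANALYTES["cortisol"]


@pytest.fixture(scope="session")
def cortisol_cohort():
    """Moderate two-group cortisol-like cohort shared across tests."""
    cfg = CohortConfig(
        analytes=(CORTISOL,), n_pairs_ie=3000, n_pairs_o=3000, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cortisol_deltas(cortisol_cohort):
    return compute_deltas(cortisol_cohort)
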