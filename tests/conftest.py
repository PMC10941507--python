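import numpy as np
import pytest

from neurograd import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for plumbing tests (fast; not used for power claims)."""
    cfg = CohortConfig(
        n_controls=4, n_patients=6, n_roi=30, n_timepoints=60,
        vertices_per_roi=20, seed=99,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions, shared across tests."""
    return generate_cohort(CohortConfig(seed=1))
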