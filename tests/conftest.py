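import numpy as np
import pytest

import heartage as ha


@pytest.fixture(scope="session")
def healthy_frame():
    """Default healthy cohort at the reference size, fixed seed."""
    return ha.cohort_frame(ha.generate_healthy(ha.CohortConfig(n=191, seed=1)))


@pytest.fixture(scope="session")
def zero_noise_frame():
    """Noise-free healthy cohort on the scorer's interior domain.

    EF spans the full decline (corrections encoded into the ESV inverse) and
    ages stay inside the mid segment's span, so the scorer inverts exactly.
    """
    cfg = ha.CohortConfig(
        n=200, seed=5, noise_sd_years=0.0, ef_jitter_sd=0.0,
        age_range=(17.0, 85.0),
    )
    return ha.cohort_frame(ha.generate_healthy(cfg))


@pytest.fixture(scope="session")
def unhealthy_frame():
    return ha.cohort_frame(ha.generate_unhealthy(ha.CohortConfig(n=366, seed=1)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
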