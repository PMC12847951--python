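import numpy as np
import pytest

from megprog.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-group cohort shared across tests (spectra mode)."""
    cfg = CohortConfig(n_hc=12, n_pd=12, n_regions=12, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from megprog.spectral import parameterize_cohort

    return parameterize_cohort(small_cohort.spectra)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
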