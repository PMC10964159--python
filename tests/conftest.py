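import dataclasses

import numpy as np
import pytest

from rdalert import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n_patients=9896, seed=1)


@pytest.fixture(scope="session")
def effect_cohort(default_config):
    """Cohort with the default true jump of -0.104 at 65.0."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def null_cohort():
    """Large cohort with no jump and no manipulation."""
    return generate_cohort(CohortConfig(n_patients=50_000, tau=0.0, seed=5))


@pytest.fixture()
def null_config():
    return CohortConfig(n_patients=6000, tau=0.0, seed=0)


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
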