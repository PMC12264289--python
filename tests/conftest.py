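"""Shared fixtures: small seeded cohorts generated once per session."""

import numpy as np
import pytest

from pulseco.population import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def small_cohort():
    """240-subject cohort with the default group distributions."""
    cfg = PopulationConfig(n_normodynamic=160, n_hyperdynamic=80, seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_cohort_groups(small_cohort):
    return np.array([s.params.group for s in small_cohort])
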