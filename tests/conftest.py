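import dataclasses

import numpy as np
import pytest

from striamap.cohort import CohortConfig, EffectsConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_control=5, n_irbd=4, n_pd=5, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def zero_dispersion_config(**kwargs) -> CohortConfig:
    """Config with every noise dispersion at zero (deterministic scores)."""
    cfg = CohortConfig(**kwargs)
    eff = dataclasses.replace(
        cfg.effects, subject_score_sigma=0.0, subject_reach_sd=0.0,
        hemisphere_reach_sd=0.0, bias_sigma=0.0)
    return dataclasses.replace(cfg, effects=eff)
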