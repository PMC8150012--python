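import numpy as np
import pandas as pd
import pytest

from foodict import synthetic_cohort as sc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return sc.EffectConfig(seed=7)


@pytest.fixture(scope="session")
def null_config():
    """All planted effects zero; no missingness."""
    return sc.EffectConfig(
        rating_effect={(g, c): 0.0 for g in sc.GROUPS for c in sc.RATED_CATEGORIES},
        weight_effect={(g, t): 0.0 for g in sc.GROUPS for t in sc.TIMEPOINTS},
        missing_rate={t: 0.0 for t in sc.TIMEPOINTS},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_trial(default_config):
    """Complete synthetic trial, 20 participants per arm."""
    return sc.generate_trial(20, default_config)


@pytest.fixture(scope="session")
def small_items(default_config):
    return sc.generate_items(default_config, n_per_cell=6)
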