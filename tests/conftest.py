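import numpy as np
import pandas as pd
import pytest

from concord.config import RunConfig
from concord.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """6 participants x 40 days with the default (noisy) generator."""
    cfg = SyntheticConfig(n_participants=6, n_days=40, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Perfect EMA, full compliance, no incidental MVPA: the pipeline should
    recover the truth table exactly."""
    cfg = SyntheticConfig(n_participants=5, n_days=60, seed=9,
                          ema_sensitivity=1.0, ema_specificity=1.0,
                          ema_compliance=1.0, wear_compliance=1.0,
                          incidental_mvpa_per_day=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def run_config():
    return RunConfig()


def random_day(rng, p_active=0.3):
    """A random 1440-slot active indicator."""
    return rng.random(1440) < p_active
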