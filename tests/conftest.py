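import numpy as np
import pandas as pd
import pytest

from votcp import synthetic_cohort as sc
from votcp.trial_designs import (
    build_discrimination_design,
    build_identification_design,
)


@pytest.fixture(scope="session")
def id_design():
    return build_identification_design(reps=10, seed=0)


@pytest.fixture(scope="session")
def disc_design():
    return build_discrimination_design(reps=5, seed=0)


@pytest.fixture(scope="session")
def default_config():
    return sc.CohortConfig()


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study (12 controls, 12 dyslexics)."""
    cfg = sc.CohortConfig(
        n_control=12, n_dys_pa=4, n_dys_vas=4, n_dys_double=2, n_dys_other=2, seed=42
    )
    participants, id_trials, disc_trials = sc.simulate_study(cfg)
    return cfg, participants, id_trials, disc_trials


def make_profile(mu=0.0, s=8.0, pid="P0001", group="CTL", **kw):
    defaults = dict(
        participant_id=pid, group=group, age_months=120,
        boundary_mu_ms=mu, precision_s_ms=s,
        pa_ability=0.0, vas_ability=0.0,
        reading_acc_latent=0.0, reading_speed_latent=0.0,
    )
    defaults.update(kw)
    return sc.LatentProfile(**defaults)


@pytest.fixture
def profile_factory():
    return make_profile
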