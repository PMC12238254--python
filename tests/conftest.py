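import numpy as np
import pytest

import orthoplan as op
from orthoplan.agent import TrainConfig
from orthoplan.env import EnvConfig
from orthoplan.planner import TreatmentPlanner


@pytest.fixture(scope="session")
def small_cohort():
    return op.sample_cohort(op.CohortConfig(n=50, seed=7))


@pytest.fixture(scope="session")
def quiet_env_config():
    """Zero-noise environment for deterministic dynamics checks."""
    return EnvConfig(noise_mm=0.0, noise_deg=0.0, noise_unit=0.0, noise_harmony=0.0)


@pytest.fixture(scope="session")
def trained_results(small_cohort):
    """One SAC training run shared across tests (cohort 50, documented step budget)."""
    tc = TrainConfig(total_steps=8_000, start_steps=500, update_every=2,
                     batch_size=128, lr=1e-3, eval_every=4_000,
                     eval_episodes=3, seed=3)
    planner = TreatmentPlanner(small_cohort, train_config=tc)
    return planner.fit()
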