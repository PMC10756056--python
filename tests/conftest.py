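"""Shared fixtures.

The full-scale case-2 experiments (100 replicates of 2000 trials, both
learners) are expensive enough to share: they back the reward-loss and
RMSE checks and are computed once per session.
"""

import numpy as np
import pytest

from flexlearn.engine import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def case2_flexible():
    return run_experiment(
        ExperimentConfig(scenario="case2", learner="flexible", n_replicates=100, seed=20240901)
    )


@pytest.fixture(scope="session")
def case2_constant():
    return run_experiment(
        ExperimentConfig(scenario="case2", learner="constant", n_replicates=100, seed=20240902)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
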