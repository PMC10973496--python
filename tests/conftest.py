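"""Shared fixtures: simulated rounds and the canonical recovery fit.

Expensive artifacts (a full simulated round, the 40-player parameter
recovery fit) are session-scoped so several test modules can share
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import socialforage as sf
from socialforage.sim import recovery_study_params

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

ROUND_SEEDS = (100, 101, 102, 103)


@pytest.fixture(scope="session")
def abm_round():
    """One full concentrated round at 25 Hz with ground truth."""
    return sf.simulate_round(sf.EnvironmentConfig.preset("concentrated"), duration=720, rng=ROUND_SEEDS[0])


@pytest.fixture(scope="session")
def abm_round_1hz(abm_round):
    return sf.resample_to_1hz(abm_round.trajectories)


@pytest.fixture(scope="session")
def abm_features(abm_round, abm_round_1hz):
    return sf.features_pipeline(abm_round_1hz, abm_round.patches, abm_round.events)


@pytest.fixture(scope="session")
def abm_rounds():
    """Four concentrated rounds (1 Hz) with pooled features and truth."""
    trajs, patches, events, truths = [], [], [], []
    for r, seed in enumerate(ROUND_SEEDS):
        out = sf.simulate_round(
            sf.EnvironmentConfig.preset("concentrated"), duration=720, rng=seed, round_id=r
        )
        trajs.append(sf.resample_to_1hz(out.trajectories))
        patches.append(out.patches)
        events.append(out.events)
        truths.append(out.truth_states)
    traj = pd.concat(trajs, ignore_index=True)
    feats = sf.features_pipeline(
        traj, pd.concat(patches, ignore_index=True), pd.concat(events, ignore_index=True)
    )
    return {
        "traj": traj,
        "features": feats,
        "truth": pd.concat(truths, ignore_index=True),
    }


@pytest.fixture(scope="session")
def recovery_truth():
    return recovery_study_params()


@pytest.fixture(scope="session")
def recovery_data(recovery_truth):
    """40 synthetic players, 2x2 conditions, sampled from the model."""
    cov = sf.simulate_covariates(n_players=40, rng=np.random.default_rng(31))
    return sf.simulate_from_model(recovery_truth, cov, rng=np.random.default_rng(1031))


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """The canonical fixed-effects fit of the recovery dataset."""
    return sf.fit(recovery_data, kind="fixed", n_draws=2000, seed=5)
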