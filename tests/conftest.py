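"""Shared fixtures: one seeded synthetic training run reused across tests.

Training the default model on the 100-frame synthetic walk takes a couple
of seconds, so the fitted model is session-scoped and shared by the
module- and acceptance-level tests that probe it.
"""

from __future__ import annotations

import numpy as np
import pytest

from aegpdm import (
    AutoEncodedGPDM,
    FallSimConfig,
    GPNoveltyDetector,
    WalkSimConfig,
    simulate_fall,
    simulate_walk,
)

WALK_SEED = 11
MODEL_SEED = 42
FALL_ONSET_S = 8.0


@pytest.fixture(scope="session")
def walk_dataset():
    return simulate_walk(WalkSimConfig(seed=WALK_SEED))


@pytest.fixture(scope="session")
def fall_dataset():
    return simulate_fall(
        WalkSimConfig(seed=WALK_SEED, duration=12.0),
        FallSimConfig(direction="forward", onset_time=FALL_ONSET_S),
    )


@pytest.fixture(scope="session")
def untrained_model(walk_dataset):
    """Default model initialized but not optimized (n_iter=0)."""
    return AutoEncodedGPDM(n_iter=0, random_state=MODEL_SEED).fit(
        walk_dataset.series.values
    )


@pytest.fixture(scope="session")
def trained_model(walk_dataset):
    """Default configuration, 500 iterations, fixed seed."""
    return AutoEncodedGPDM(random_state=MODEL_SEED).fit(
        walk_dataset.series.values
    )


@pytest.fixture(scope="session")
def detector(trained_model):
    det = GPNoveltyDetector(random_state=0).fit(
        trained_model.latent_samples_
    )
    det.choose_threshold(det.score_samples(det.support_))
    return det


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
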