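"""Shared fixtures: the reference synthetic dataset and trained network pair.

Training fixtures are session-scoped — the reference pair takes ~30 s of
CPU and is reused by the training, experiment and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from repnonuniq import (
    ExperimentConfig,
    SyntheticImageConfig,
    TrainConfig,
    generate_train_test,
    run_all,
    train_pair_scheme1,
)
from repnonuniq.nets import REFERENCE_TOKENS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Reference study conditions: 10 balanced classes of 16x16 RGB images,
#: 100 train / 50 test per class, full-contrast templates, sd-0.05 pixel
#: noise, +/-1 px jitter.
REFERENCE_DATA_CONFIG = SyntheticImageConfig(seed=1)

REFERENCE_TRAIN_CONFIG = TrainConfig(architecture=REFERENCE_TOKENS, seed=11)

#: Small configuration for fast training-semantics tests (not the
#: reference study conditions; used only where the property under test
#: does not depend on reaching high accuracy).
TINY_DATA_CONFIG = SyntheticImageConfig(per_class_count=20, seed=3)
TINY_ARCH = ["Conv3-4", "Max-pool", "Fc-16", "Fc-10"]


@pytest.fixture(scope="session")
def reference_data():
    return generate_train_test(REFERENCE_DATA_CONFIG)


@pytest.fixture(scope="session")
def tiny_data():
    return generate_train_test(TINY_DATA_CONFIG)


@pytest.fixture(scope="session")
def reference_pair(reference_data):
    """Scheme-1 similar-performing pair on the reference dataset."""
    train, test = reference_data
    return train_pair_scheme1(
        REFERENCE_TRAIN_CONFIG, train, test, seed1=11, seed2=12
    )


@pytest.fixture(scope="session")
def reference_net1(reference_pair):
    return reference_pair.net1


@pytest.fixture(scope="session")
def experiment_reports(reference_pair, reference_data):
    """All four analyses on the reference pair with a shared seed."""
    _, test = reference_data
    return run_all(reference_pair, test, ExperimentConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
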