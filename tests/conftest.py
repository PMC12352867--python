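import warnings

import numpy as np
import pytest

from instasub import (
    SyntheticConfig,
    generate_session,
    preprocess_bundle,
)
from instasub.pipeline import pooled_epoch_stats

warnings.filterwarnings("ignore", category=UserWarning)


SMALL = dict(
    n_units=16,
    n_mn=10,
    n_ae=3,
    n_ao=1,
    n_ns=2,
    trials_per_object=8,
    seed=42,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(**SMALL)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """One small synthetic session: (exec bundle, obs bundle, ground truth)."""
    exec_bundle, gt = generate_session(small_cfg, "execution")
    obs_bundle, _ = generate_session(small_cfg, "observation")
    return exec_bundle, obs_bundle, gt


@pytest.fixture(scope="session")
def small_tensors(small_session):
    exec_bundle, obs_bundle, _ = small_session
    stats = pooled_epoch_stats([exec_bundle, obs_bundle])
    te = preprocess_bundle(exec_bundle, stats)
    to = preprocess_bundle(obs_bundle, stats)
    return te, to


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
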