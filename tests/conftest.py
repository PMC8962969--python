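import dataclasses

import numpy as np
import pytest

from fedhar import evaluation, federated, neural
from fedhar.synthetic import SyntheticConfig, build_dataset


@pytest.fixture(scope="session")
def separable_3class():
    """Noise-free 3-class dataset with 70% of window labels hidden."""
    cfg = SyntheticConfig(
        n_subjects=4,
        activities=("standing", "walking", "jogging"),
        positions=("arm", "waist"),
        windows_per_subject_activity=10,
        n_channels=3,
        noise_std=0.0,
        unlabeled_fraction=0.7,
        seed=11,
    )
    ds, truth = build_dataset(cfg, feature_count=15)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def desk_run_config():
    """A ~1000-window noise-free scenario for end-to-end runs."""
    syn = SyntheticConfig(
        n_subjects=5,
        activities=("standing", "walking", "jogging", "lying"),
        positions=("arm", "waist"),
        windows_per_subject_activity=25,
        n_channels=3,
        noise_std=0.0,
        unlabeled_fraction=0.7,
        seed=5,
    )
    return evaluation.RunConfig(
        synthetic=syn,
        feature_count=15,
        hidden=8,
        qlearner=dataclasses.replace(
            evaluation.RunConfig().qlearner, episodes=15, steps_per_episode=150
        ),
        federated_cfg=federated.FederatedConfig(
            n_clients=5,
            rounds=10,
            local=neural.TrainingConfig(iterations=3, seed=1),
            seed=2,
        ),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
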