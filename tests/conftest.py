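"""Shared fixtures.

The expensive nested-CV runs (RF-OMC on the 70 x 1000 planted-signal
dataset) are session-scoped so several tests can interrogate one run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gemresponse.cv import CVConfig, run_merged_cv
from gemresponse.models import ModelSpec, make_model
from gemresponse.omc import OMCConfig
from gemresponse.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_profile,
    labels_from_cohort,
)


@pytest.fixture(scope="session")
def signal_config() -> SyntheticConfig:
    """The emulated study conditions: n=70, 41/29 split, 1,000 features,
    5 informative at a standardized shift of 1.5."""
    return SyntheticConfig()


@pytest.fixture(scope="session")
def signal_dataset(signal_config):
    """(X, y) with planted signal; X is a samples x features DataFrame."""
    cohort = generate_cohort(signal_config)
    y = labels_from_cohort(cohort)
    profile = generate_profile(signal_config, y)
    return profile.values, y


@pytest.fixture(scope="session")
def five_seed_cv() -> CVConfig:
    return CVConfig(k=10, seeds=(0, 1, 2, 3, 4))


@pytest.fixture(scope="session")
def coarse_omc() -> OMCConfig:
    """10-fold inner CV over the coarse top-k grid {2, 8, 14, 20, 26}."""
    return OMCConfig(inner_k=10, k_step=6)


@pytest.fixture(scope="session")
def rf_omc_result(signal_dataset, five_seed_cv, coarse_omc):
    """RF with OMC selection on the planted-signal dataset, 5 seeds."""
    X, y = signal_dataset
    factory = make_model(ModelSpec("rf", "omc"), omc_config=coarse_omc)
    return run_merged_cv(X, y, factory, five_seed_cv)


@pytest.fixture(scope="session")
def rf_all_result(signal_dataset, five_seed_cv):
    """All-features RF on the same dataset and seeds."""
    X, y = signal_dataset
    factory = make_model(ModelSpec("rf", "all_features"))
    return run_merged_cv(X, y, factory, five_seed_cv)


class OraclePredictor:
    """Scores every sample with its true label (perfect classifier)."""

    score_type = "probability"

    def __init__(self, label_map):
        self.label_map = label_map

    def fit(self, X, y):
        return self

    def score_samples(self, X):
        return np.array([self.label_map[s] for s in X.index], dtype=float)


class MajorityPredictor:
    """Predicts its training majority class for everything (constant)."""

    score_type = "probability"

    def __init__(self):
        self.majority = 0

    def fit(self, X, y):
        self.majority = int(np.mean(y) > 0.5)
        return self

    def score_samples(self, X):
        return np.full(len(X), float(self.majority))


@pytest.fixture
def oracle_factory():
    def build(X, y):
        label_map = dict(zip(X.index, y))
        return lambda seed: OraclePredictor(label_map)

    return build


@pytest.fixture
def majority_factory():
    return lambda seed: MajorityPredictor()
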