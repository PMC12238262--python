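"""Shared fixtures.

The expensive artifacts (trained classifier, trained VAE) are session-scoped
so the end-to-end property tests share one training run each.  All sizes
here are the scaled-down study conditions: 2000 surrogate trajectories and
50 epochs for the generative model, 1000 trajectories per class for the
six-process benchmark classifier.
"""

from __future__ import annotations

import numpy as np
import pytest

from lptraj.classifier import ClassifierConfig, train_classifier
from lptraj.core import (LabeledTrajectoryDataset, generate_surrogate_lptem,
                         normalize_trajectory)
from lptraj.loss import LossWeights
from lptraj.simulate import make_labeled_dataset
from lptraj.vae import ModelConfig, train_vae

#: scaled-down VAE architecture and training weights used by the
#: end-to-end studies (KL weight 4 keeps the aggregate posterior close
#: enough to the prior for meaningful prior-sample generation)
STUDY_VAE_CONFIG = dict(T=200, embed_dim=32, n_heads=4, n_attn_layers=2,
                        patch=10, batch_size=64, epochs=50,
                        learning_rate=2e-3, seed=0)
STUDY_LOSS_WEIGHTS = LossWeights(kl=4.0)


@pytest.fixture(scope="session")
def surrogate_train() -> LabeledTrajectoryDataset:
    """2000 normalized surrogate liquid-cell trajectories (T = 200)."""
    raw = generate_surrogate_lptem(2000, 200, seed=11)
    return LabeledTrajectoryDataset(
        [normalize_trajectory(t)[0] for t in raw.trajectories], raw.labels)


@pytest.fixture(scope="session")
def trained_vae(surrogate_train):
    """VAE trained 50 epochs on the surrogate ensemble."""
    cfg = ModelConfig(**STUDY_VAE_CONFIG)
    model, history = train_vae(surrogate_train, cfg, STUDY_LOSS_WEIGHTS)
    return model, history


@pytest.fixture(scope="session")
def benchmark_6class() -> LabeledTrajectoryDataset:
    """Balanced six-process benchmark: 1000 trajectories per class, T = 200."""
    return make_labeled_dataset(n_per_class=1000, T=200, seed=21)


@pytest.fixture(scope="session")
def classifier_6class(benchmark_6class):
    clf, history = train_classifier(benchmark_6class,
                                    ClassifierConfig(seed=0))
    return clf


@pytest.fixture(scope="session")
def classifier_7class(surrogate_train):
    """Classifier over the six simulated classes plus the surrogate class."""
    sim = make_labeled_dataset(n_per_class=400, T=200, seed=31)
    trajs = sim.trajectories + surrogate_train.trajectories[:400]
    labels = sim.labels + surrogate_train.labels[:400]
    ds = LabeledTrajectoryDataset(trajs, labels)
    clf, history = train_classifier(ds, ClassifierConfig(seed=1))
    return clf


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
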