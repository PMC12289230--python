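"""Shared fixtures: tiny synthetic datasets and the one expensive trained
model reused by the learning-dependent checks."""

from __future__ import annotations

import numpy as np
import pytest

from gofuse.model import ModelConfig
from gofuse.pipeline import run_experiment
from gofuse.synthetic import SyntheticSpec, make_dataset
from gofuse.train import TrainConfig

# study conditions of the planted learning-sanity experiment: 200 proteins of
# 30-60 residues, 16 leaf terms, no label noise; CPU-scale training recipe
# (small batches + dropout regularize the 140-protein training split)
SANITY_SPEC = SyntheticSpec(n_proteins=200, length_range=(30, 60), n_terms=16,
                            label_noise=0.0, seed=1)
SANITY_TRAIN = TrainConfig(learning_rate=3e-4, batch_size=8, max_epochs=50,
                           patience=5, seed=1)
SANITY_MODEL = ModelConfig(dropout=0.5, seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 proteins, 8 leaf terms — fast enough for per-module tests."""
    return make_dataset(SyntheticSpec(n_proteins=30, n_terms=8, seed=2))


@pytest.fixture(scope="session")
def sanity_dataset():
    return make_dataset(SANITY_SPEC)


@pytest.fixture(scope="session")
def sanity_experiment(sanity_dataset):
    """One CPU training run at the study conditions, shared across tests."""
    return run_experiment(sanity_dataset, SANITY_TRAIN, SANITY_MODEL)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
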