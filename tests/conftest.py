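"""Shared fixtures.

The heavier fixtures (trained models on the reference synthetic benchmark) are
session-scoped so several tests can interrogate one training run.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from opfddl import SynthConfig, TrainConfig, fit, generate_dataset

# the reference benchmark: generator defaults (C=3, R=3, m=20, n=300, SNR 10 dB)
BENCH_SEED = 7
BENCH_TRAIN = TrainConfig(atoms_per_class=10, seed=BENCH_SEED)


@pytest.fixture(scope="session", autouse=True)
def _quiet_convergence_warnings():
    warnings.filterwarnings("ignore", message="Orthogonal matching pursuit")
    yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bench_dataset():
    """Generator-default benchmark dataset (SNR 10 dB, seed 7)."""
    dataset, truth = generate_dataset(SynthConfig(seed=BENCH_SEED))
    return dataset, truth


@pytest.fixture(scope="session")
def bench_model(bench_dataset):
    """Model trained on the benchmark dataset."""
    dataset, _ = bench_dataset
    return fit(dataset, BENCH_TRAIN)


@pytest.fixture(scope="session")
def noiseless_dataset():
    dataset, truth = generate_dataset(SynthConfig(seed=BENCH_SEED, snr_db=None))
    return dataset, truth


@pytest.fixture(scope="session")
def noiseless_model(noiseless_dataset):
    dataset, _ = noiseless_dataset
    return fit(dataset, BENCH_TRAIN)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, fast dataset for unit-level training tests."""
    cfg = SynthConfig(n_classes=2, n_bands=2, n_features=10, latent_dim=6,
                      atoms_per_class=3, samples_per_class=25, nonzeros=2,
                      snr_db=15.0, seed=3)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth


@pytest.fixture
def tiny_config():
    return TrainConfig(atoms_per_class=3, max_iters=8, seed=3, ksvd_iters=5,
                       ksvd_sparsity=2)
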