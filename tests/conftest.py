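"""Shared fixtures: synthetic datasets and a trained toy GAN.

The expensive fixtures are session-scoped so the benchmark dataset is
generated once and the GAN is trained once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vigilgan.synthetic import generate_feature_dataset
from vigilgan.training import ConditionalEEGGAN


@pytest.fixture(scope="session")
def small_dataset():
    """40 windows per class; quick fixture for unit-level checks."""
    X, y, perclos_values = generate_feature_dataset(n_per_class=(40, 40), seed=7)
    return X, y, perclos_values


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default synthetic benchmark: 200 segments per class, seeded."""
    X, y, perclos_values = generate_feature_dataset(n_per_class=(200, 200), seed=11)
    return X, y, perclos_values


@pytest.fixture(scope="session")
def benchmark_split(benchmark_dataset):
    """Deterministic train-pool / held-out-test split of the benchmark."""
    X, y, _ = benchmark_dataset
    rng = np.random.default_rng(23)
    idx = rng.permutation(len(y))
    n_test = len(y) // 4
    test, train = idx[:n_test], idx[n_test:]
    return (X[train], y[train]), (X[test], y[test])


@pytest.fixture(scope="session")
def trained_gan(benchmark_split):
    """A compact conditional GAN trained briefly on the benchmark train pool.

    The benchmark protocol trains the auxiliary head on generated samples
    too (the original auxiliary-classifier GAN composition) — at this step
    budget that is what makes the generator's class-conditioning converge;
    see docs/methods.md.
    """
    (X_train, y_train), _ = benchmark_split
    gan = ConditionalEEGGAN(steps=150, batch_size=16, seed=3, cls_on_fake_for_d=True)
    gan.fit(X_train, y_train)
    return gan
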