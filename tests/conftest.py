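"""Shared fixtures: synthetic acquisitions and one trained pipeline.

The heavy objects are session-scoped so the whole suite trains the
pipeline once.  Seeds are fixed; everything downstream is deterministic.
"""

import numpy as np
import pytest

import rehabband as rb

TRAIN_SEED = 11
TEST_SEED = 1011


@pytest.fixture(scope="session")
def train_ds() -> rb.SyntheticDataset:
    """Five training subjects, 50 reps per action (the acquisition protocol)."""
    return rb.generate_dataset(n_subjects=5, reps_per_action=50, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def test_ds() -> rb.SyntheticDataset:
    """Five unseen subjects, same protocol, disjoint seed."""
    return rb.generate_dataset(n_subjects=5, reps_per_action=50, seed=TEST_SEED)


@pytest.fixture(scope="session")
def bundle(train_ds) -> rb.PipelineBundle:
    """Autoencoder + SVM ensemble trained on the training subjects."""
    return rb.train_pipeline(train_ds.features, train_ds.labels, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
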