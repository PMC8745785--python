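"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from apnea_bof import (
    ClassifierSpec,
    EffectConfig,
    SimConfig,
    reject_artifacts,
    segment_windows,
    simulate_corpus,
    zero_mean,
)
from apnea_bof.pipeline import compute_features


@pytest.fixture(scope="session")
def tiny_corpus():
    """Two short subjects with the default planted apnea contrast."""
    cfg = SimConfig(n_subjects=2, minutes_per_subject=20, artifact_rate=0.0, seed=17)
    records, manifest = simulate_corpus(cfg)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def tiny_windows(tiny_corpus):
    _, records, _ = tiny_corpus
    windows = []
    for rec in records:
        windows.extend(segment_windows(zero_mean(rec), 60))
    kept, _ = reject_artifacts(windows)
    return kept


@pytest.fixture(scope="session")
def tiny_features(tiny_windows):
    """High-band BofVectors + codebook for the tiny corpus (shared, slow)."""
    vectors, codebook = compute_features(
        tiny_windows, "high", vocabulary_size=40, seed=5
    )
    return vectors, codebook


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def svm_spec():
    return ClassifierSpec("svm", seed=0)
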