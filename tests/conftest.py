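"""Shared fixtures.

The trained toy model is expensive (~1-2 min on one CPU), so it is built
once per session and shared by the predictor tests and the acceptance
checks that need a fitted model.
"""

from __future__ import annotations

import numpy as np
import pytest

from wellpred.model import FramePredictor, PredictorConfig
from wellpred.wellsim import SimConfig, make_growing_disk_corpus

TOY_TRAIN_N = 60
TOY_VAL_N = 10
TOY_ITERATIONS = 300  # enough to clear the persistence baseline by ~5x


@pytest.fixture(scope="session")
def toy_corpus():
    """Deterministic growing-disk corpus: 70 videos, 20 frames, 16x16."""
    return make_growing_disk_corpus(n_videos=TOY_TRAIN_N + TOY_VAL_N,
                                    n_frames=20, side=16, rng_seed=0)


@pytest.fixture(scope="session")
def toy_split(toy_corpus):
    seqs = toy_corpus.sequences
    return seqs[:TOY_TRAIN_N], seqs[TOY_TRAIN_N:]


@pytest.fixture(scope="session")
def toy_config():
    return PredictorConfig(n_layers=2, hidden_channels=8, conv_kernel=3,
                           patch_size=4, learning_rate=3e-3, batch_size=8,
                           max_iterations=TOY_ITERATIONS, eval_interval=100,
                           rng_seed=0)


@pytest.fixture(scope="session")
def toy_results(toy_split, toy_config):
    train, val = toy_split
    return FramePredictor(train, val, config=toy_config).fit()


@pytest.fixture
def sim_config():
    return SimConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
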