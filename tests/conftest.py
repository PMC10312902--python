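"""Shared fixtures.

The expensive end-to-end artifacts (a synthetic dataset, trained codecs,
a trained transformer bundle) are built once per session and shared by
the functional-recovery and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from seq2loc.image_codec import CodecConfig, train_codec
from seq2loc.pipeline import MINI, train_pipeline
from seq2loc.synthetic_cells import generate_records

DATASET_SEED = 7
TRAIN_SEED = 0
N_TRAIN = 200
N_VAL = 40


@pytest.fixture(scope="session")
def mini_records():
    """240 balanced samples: 200 train + 40 val (10 per class each split)."""
    return generate_records(N_TRAIN + N_VAL, seed=DATASET_SEED,
                            config=MINI.generator)


@pytest.fixture(scope="session")
def train_records(mini_records):
    return mini_records[:N_TRAIN]


@pytest.fixture(scope="session")
def val_records(mini_records):
    return mini_records[N_TRAIN:]


@pytest.fixture(scope="session")
def trained_bundle(train_records):
    """Full three-phase training at mini scale (codecs + transformer)."""
    return train_pipeline(train_records, MINI, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def threshold_codec(train_records):
    """A threshold-channel codec trained on a 160-image subset."""
    imgs = [r.protein_image for r in train_records[:160]]
    codec, curve = train_codec(imgs, "threshold",
                               CodecConfig(epochs=50, seed=3))
    codec._loss_curve = curve
    return codec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
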