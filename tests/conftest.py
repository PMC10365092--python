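"""Shared fixtures: small phantom datasets and a trained tiny model.

The trained model is session-scoped because desk-scale training takes a
few minutes; every test that needs a non-trivial network shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

import tractuq as tq


@pytest.fixture(scope="session")
def phantom_spec() -> tq.PhantomSpec:
    return tq.PhantomSpec()


@pytest.fixture(scope="session")
def phantom_dataset(phantom_spec):
    """8 phantoms, seed 7: first 6 train, last 2 held out."""
    return tq.make_dataset(8, phantom_spec, seed=7)


@pytest.fixture(scope="session")
def prepared_subjects(phantom_dataset):
    return tq.prepare_subjects(phantom_dataset)


@pytest.fixture(scope="session")
def single_subject(prepared_subjects):
    return prepared_subjects[0]


TINY_TRAIN = dict(
    epochs=90,
    initial_lr=0.02,
    lr_halving_period=30,
    patch_size=16,
    patches_per_subject=8,
    batch_size=2,
    augmentation_range_deg=20.0,
    seed=0,
)


@pytest.fixture(scope="session")
def trained_model(prepared_subjects):
    """Tiny-profile network trained on the first 6 phantoms (seed 7 data)."""
    cfg = tq.ModelConfig.tiny(out_channels=3, in_channels=15,
                              dropout_rate=0.25, base_filters=16)
    model = tq.build_model(cfg, seed=1)
    tq.train(model, prepared_subjects[:6], tq.TrainConfig(**TINY_TRAIN))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
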