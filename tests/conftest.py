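"""Shared fixtures: small synthetic splits and a mini pretraining result."""

import numpy as np
import pytest

from ecgfewshot.nn import TINY_ENCODER_SPEC
from ecgfewshot.preprocess import SplitSpec, build_splits
from ecgfewshot.ssl_pretrain import PretrainConfig, pretrain


@pytest.fixture(scope="session")
def mini_splits():
    """Small but complete split family used by the unit tests."""
    spec = SplitSpec(
        few_shot_n_per_class=4,
        reference_n=20,
        val_n_per_class=2,
        test_size=40,
        unlabeled_n=16,
        seed=7,
    )
    return build_splits(spec)


@pytest.fixture(scope="session")
def mini_pretrain(mini_splits):
    """Two-epoch contrastive pretraining on the mini pool (tiny encoder)."""
    return pretrain(
        mini_splits.unlabeled,
        enc_spec=TINY_ENCODER_SPEC,
        cfg=PretrainConfig(batch_pairs=8, epochs=2, seed=3),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
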