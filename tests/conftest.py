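"""Shared fixtures: a small trained classifier and synthetic datasets.

The "tiny" model trains in a few seconds on short motif-planted sequences
against fully shuffled negatives; it is shared session-wide by every test
that needs a fitted classifier but does not probe full-scale behaviour.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from casminer.net import EncoderSpec, ModelConfig, train
from casminer.shuffle import ShuffleConfig, build_negative_dataset
from casminer.synth import Motif, SynthSpec, make_positive_set

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

TINY_MOTIFS = (
    Motif("DIGTNSVGWA", 0.15, jitter=10),
    Motif("HMIKFRGHFL", 0.55, jitter=10),
    Motif("WDPKKYGGFD", 0.85, jitter=8),
)


def tiny_spec(seed: int = 11, n: int = 120) -> SynthSpec:
    return SynthSpec(n_sequences=n, length_range=(150, 220),
                     motifs=TINY_MOTIFS, seed=seed)


def tiny_config(seed: int = 11, epochs: int = 20) -> ModelConfig:
    return ModelConfig(embedding_dim=16, conv_filters=(24, 24), kernel_size=7,
                       pool_size=4, lstm_units=24, dense_units=16,
                       epochs=epochs, batch_size=16,
                       split_seed=seed, init_seed=seed)


@pytest.fixture(scope="session")
def tiny_positives():
    return make_positive_set(tiny_spec())


@pytest.fixture(scope="session")
def tiny_negatives(tiny_positives):
    return build_negative_dataset(
        tiny_positives, ShuffleConfig(threshold=1.0, seed=11))


@pytest.fixture(scope="session")
def tiny_model(tiny_positives, tiny_negatives):
    """A quickly trained classifier on the tiny motif problem."""
    clf, report = train(tiny_positives, tiny_negatives, tiny_config(),
                        EncoderSpec(max_len=220))
    return clf, report
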