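import numpy as np
import pytest

from pixseq.labels import LabeledSequence
from pixseq.model import ModelConfig, SeqTaggerModel
from pixseq.vocab import PixelDictionary


@pytest.fixture
def toy_dictionary():
    """12-token single-band dictionary with identity tuples."""
    return PixelDictionary(
        levels_per_band=12, band_count=1,
        band_min=np.zeros(1), band_max=np.ones(1),
        token_of={(i,): i for i in range(12)},
    )


@pytest.fixture
def toy_config():
    """Small float64 tagger configuration for fast, precise unit tests."""
    return ModelConfig(encoder_units=8, decoder_lstm_units=8, indrnn_units=6,
                       label_embedding_dim=4, epochs=2, batch_size=8,
                       dtype="float64", seed=0)


@pytest.fixture
def toy_model(toy_dictionary, toy_config):
    rng = np.random.default_rng(3)
    emb = rng.normal(size=(toy_dictionary.m, 8))
    return SeqTaggerModel(toy_config, toy_dictionary, emb)


@pytest.fixture
def toy_dataset(toy_dictionary):
    """16 random labelled windows over the toy vocabulary."""
    rng = np.random.default_rng(3)
    return [
        LabeledSequence(tokens=rng.integers(0, toy_dictionary.m, 10),
                        labels=rng.integers(0, 3, 10), row=i, col=0, axis="row")
        for i in range(16)
    ]
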