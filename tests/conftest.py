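import numpy as np
import pytest

from mlee.model import ModelConfig, TrainConfig, train
from mlee.schema import default_schema
from mlee.synth import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small deterministic corpus shared by unit tests."""
    return generate_corpus(GeneratorConfig(n_documents=36, seed=3))


@pytest.fixture(scope="session")
def tiny_bundle(tiny_corpus, schema):
    """A deliberately small, briefly trained model for plumbing tests.

    Not accurate — unit tests assert structure and contracts, not quality.
    """
    mc = ModelConfig(embed_dim=32, ffn_dim=48, rnn_dim=16, n_layers=1, seed=5)
    tc = TrainConfig(epochs=6, batch_size=12, seed=5)
    return train(tiny_corpus, schema, mc, tc)
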