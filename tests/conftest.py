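import numpy as np
import pytest

from symptomnet.model import ModelConfig
from symptomnet.synthetic import GeneratorConfig, gen_corpus
from symptomnet.training import TrainConfig, train


@pytest.fixture(scope="session")
def small_corpus():
    """40-interview synthetic corpus shared across training/saliency tests."""
    return gen_corpus(GeneratorConfig(n_interviews=40, seed=7), (0.7, 0.15, 0.15))


#: Model/train settings for quick from-scratch runs on synthetic corpora.
TINY_MODEL = dict(d_turn=64, hidden=48, attn_dim=16, head_hidden=64)
TINY_TRAIN = dict(learning_rate=3e-3, batch_size=4)


@pytest.fixture(scope="session")
def tiny_trained(small_corpus):
    """A symptom-head model fit on the small corpus (30 epochs)."""
    mc = ModelConfig(head_type="symptoms8", **TINY_MODEL)
    tc = TrainConfig(epochs=30, seeds=(0, 1), **TINY_TRAIN)
    return train(small_corpus, mc, tc, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
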