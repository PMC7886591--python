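import numpy as np
import pytest

from cnnsad import embedding, records


@pytest.fixture(scope="session")
def corpus200():
    """Small default-proportion corpus shared across tests."""
    return records.generate_corpus(records.GeneratorConfig(n_records=200, seed=11))


@pytest.fixture(scope="session")
def trained_embedding(corpus200):
    cfg = embedding.SkipGramConfig(dim_k=8, window_n=2, epochs=2, seed=11)
    return embedding.train_skipgram(corpus200, cfg)


@pytest.fixture(scope="session")
def encoded200(corpus200, trained_embedding):
    return embedding.encode_corpus(corpus200, trained_embedding, 56).astype(np.float32)


@pytest.fixture()
def toy_embedding():
    """Hand-built 4-dimensional embedding over a tiny fixed vocabulary."""
    vocab = [embedding.PAD, embedding.UNK, "a", "b", "c"]
    rng = np.random.default_rng(5)
    vectors = rng.normal(size=(len(vocab), 4))
    vectors[0] = 0.0
    return embedding.EmbeddingModel(vocabulary=vocab, vectors=vectors)
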