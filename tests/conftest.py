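import numpy as np
import pytest

from drugrelink.hetnet import build_association_matrix, build_heterogeneous_network
from drugrelink.pair_cnn import CNNConfig
from drugrelink.similarity import SimilarityMatrix
from drugrelink.vgae import NodeEmbeddings


@pytest.fixture
def tiny_net():
    """2 drugs x 2 diseases with one association and mild similarities."""
    m_r = SimilarityMatrix(["r1", "r2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
    m_d = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.6], [0.6, 1.0]]))
    m_rd = build_association_matrix([("r1", "d1")], ["r1", "r2"], ["d1", "d2"])
    return build_heterogeneous_network(m_r, m_d, m_rd)


@pytest.fixture
def small_emb():
    rng = np.random.default_rng(7)
    return NodeEmbeddings(rng.standard_normal((5, 4)), n_r=3, n_d=2)


def tiny_cnn_config(**overrides) -> CNNConfig:
    """Geometry that fits d1=4..8 embeddings, for fast unit tests."""
    kw = dict(n_conv=2, filters=((2, 2), (1, 2), (1, 2)), pools=((1, 1), (1, 2), (1, 1)),
              fc_sizes=(8, 8, 4), epochs=5, batch_size=16)
    kw.update(overrides)
    return CNNConfig(**kw)
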