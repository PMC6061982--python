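import numpy as np
import pytest

from semindex.corpus_io import Corpus, Document, EmbeddingTable
from semindex.synthetic import SyntheticSpec, generate_all


@pytest.fixture
def tiny_corpus():
    docs = [
        Document(id="d1", title="alpha beta", abstract="gamma alpha",
                 labels={"A"}, tokens=["alpha", "beta", "gamma", "alpha"]),
        Document(id="d2", title="beta delta", abstract="delta",
                 labels={"B"}, tokens=["beta", "delta", "delta"]),
        Document(id="d3", title="alpha delta", abstract="",
                 labels={"A", "B"}, tokens=["alpha", "delta"]),
    ]
    return Corpus(docs)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(7)
    words = ["alpha", "beta", "gamma", "delta", "c1", "c2", "c3", "ORG"]
    return EmbeddingTable(
        dimension=3,
        entries={w: rng.standard_normal(3) for w in words},
        unknown_vector=np.zeros(3),
    )


@pytest.fixture(scope="session")
def synth_bundle():
    """Medium synthetic dataset shared across slower tests."""
    spec = SyntheticSpec(n_clusters=2, labels_per_cluster=3, docs_per_label=30,
                         word_dim=8, seed=11)
    return spec, generate_all(spec)
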