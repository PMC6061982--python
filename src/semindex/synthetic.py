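"""Seeded generators for corpora with label-dependent word distributions.

The generators emit exactly the file formats the I/O layer reads, so
generated data is indistinguishable from real inputs: a JSON-lines corpus,
word and label embedding tables in word2vec text format, a TSV category
map and a TSV entity lexicon.

Structure of the generated data:

* label embeddings form planted clusters (centers on a sphere of radius
  ``separation``, unit Gaussian noise);
* each label owns a sub-vocabulary with a Zipf word distribution plus a
  pool of shared background words;
* documents sample 1-3 labels, Poisson lengths, and words from the mixture
  of their labels' distributions; label frequencies follow a geometric
  imbalance profile;
* a fraction of each label's words are anchor words carrying 1-3
  categories tied to the label's cluster;
* multi-token entity phrases (with deliberate prefix ambiguity to exercise
  longest-match tagging) are inserted at a configurable rate;
* word embeddings are the owning label's signature vector plus noise.

Vocabulary strings are chosen so that preprocessing (stopword removal +
stemming) leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Corpus, Document, EmbeddingTable

__all__ = ["SyntheticSpec", "generate_label_space", "generate_corpus", "generate_all"]


@dataclass
class SyntheticSpec:
    n_clusters: int = 2
    labels_per_cluster: int = 4
    label_dim: int = 8
    separation: float = 10.0
    label_noise: float = 1.0
    vocab_per_label: int = 30
    n_background_words: int = 20
    docs_per_label: int = 50
    imbalance_ratio: float = 1.0
    mean_length: float = 30.0
    multi_label_rate: float = 0.3
    n_entities: int = 10
    entity_rate: float = 0.1
    anchor_fraction: float = 0.3
    word_dim: int = 10
    word_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "labels_per_cluster", "label_dim",
                     "vocab_per_label", "docs_per_label", "word_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")

    @property
    def n_labels(self) -> int:
        return self.n_clusters * self.labels_per_cluster

    @property
    def n_documents(self) -> int:
        return self.n_labels * self.docs_per_label


def generate_label_space(
    spec: SyntheticSpec,
) -> tuple[list[str], dict[str, np.ndarray], dict[str, int]]:
    """Labels, their embedding vectors and the planted cluster partition."""
    rng = np.random.default_rng(spec.seed)
    centers = rng.standard_normal((spec.n_clusters, spec.label_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= spec.separation
    labels: list[str] = []
    embeddings: dict[str, np.ndarray] = {}
    partition: dict[str, int] = {}
    for c in range(spec.n_clusters):
        for i in range(spec.labels_per_cluster):
            lab = f"lab{c}x{i}"
            labels.append(lab)
            embeddings[lab] = centers[c] + spec.label_noise * rng.standard_normal(
                spec.label_dim
            )
            partition[lab] = c
    return labels, embeddings, partition


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(
    spec: SyntheticSpec, labels: list[str], partition: dict[str, int]
) -> tuple[Corpus, EmbeddingTable, dict[str, list[str]], dict[tuple[str, ...], str]]:
    """Corpus + word embeddings + category map + entity lexicon.

    Deterministic given the spec (the corpus stream uses its own seed
    offset so that label-space and corpus randomness are independent).
    """
    rng = np.random.default_rng(spec.seed + 1)

    # per-label sub-vocabularies; word strings are stem- and stopword-proof
    label_vocab = {
        lab: [f"q{li}w{j}1" for j in range(spec.vocab_per_label)]
        for li, lab in enumerate(labels)
    }
    background = [f"bg{j}1" for j in range(spec.n_background_words)]

    # word embeddings: label signature + noise
    signatures = {
        lab: 2.0 * rng.standard_normal(spec.word_dim) for lab in labels
    }
    entries: dict[str, np.ndarray] = {}
    for lab in labels:
        for word in label_vocab[lab]:
            entries[word] = signatures[lab] + spec.word_noise * rng.standard_normal(
                spec.word_dim
            )
    for word in background:
        entries[word] = spec.word_noise * rng.standard_normal(spec.word_dim)

    # category map: anchors carry categories named after their cluster
    category_map: dict[str, list[str]] = {}
    for li, lab in enumerate(labels):
        cluster = partition[lab]
        n_anchor = int(round(spec.anchor_fraction * spec.vocab_per_label))
        for j in range(n_anchor):
            word = label_vocab[lab][j]
            n_cats = int(rng.integers(1, 4))
            category_map[word] = [f"cat{cluster}x{t}1" for t in range(n_cats)]
    for word in sorted({c for cats in category_map.values() for c in cats}):
        entries[word] = spec.word_noise * rng.standard_normal(spec.word_dim)

    # entity lexicon: two-token phrases; ~10% also list the bare prefix
    entity_lexicon: dict[tuple[str, ...], str] = {}
    entity_phrases: list[tuple[str, ...]] = []
    for e in range(spec.n_entities):
        cls = f"class{e % max(1, spec.n_clusters)}1"
        phrase = (f"ent{e}a1", f"ent{e}b1")
        entity_lexicon[phrase] = cls
        entity_phrases.append(phrase)
        if e % 10 == 0:
            entity_lexicon[(phrase[0],)] = cls
        for tok in phrase:
            entries[tok] = spec.word_noise * rng.standard_normal(spec.word_dim)

    embeddings = EmbeddingTable(
        dimension=spec.word_dim,
        entries=entries,
        unknown_vector=np.zeros(spec.word_dim),
    )

    # geometric imbalance profile over labels
    n_labels = len(labels)
    if n_labels > 1 and spec.imbalance_ratio != 1.0:
        ratios = spec.imbalance_ratio ** (
            np.arange(n_labels) / (n_labels - 1)
        )
    else:
        ratios = np.ones(n_labels)
    label_probs = ratios / ratios.sum()

    zipf = _zipf_weights(spec.vocab_per_label)
    documents: list[Document] = []
    for doc_id in range(spec.n_documents):
        primary = int(rng.choice(n_labels, p=label_probs))
        doc_labels = {labels[primary]}
        if rng.random() < spec.multi_label_rate and n_labels > 1:
            n_extra = int(rng.integers(1, 3))
            extras = rng.choice(
                [i for i in range(n_labels) if i != primary],
                size=min(n_extra, n_labels - 1),
                replace=False,
            )
            doc_labels.update(labels[int(i)] for i in extras)
        length = max(4, int(rng.poisson(spec.mean_length)))
        chosen = sorted(doc_labels)
        tokens: list[str] = []
        while len(tokens) < length:
            if spec.n_background_words and rng.random() < 0.1:
                tokens.append(background[int(rng.integers(spec.n_background_words))])
            else:
                lab = chosen[int(rng.integers(len(chosen)))]
                tokens.append(
                    label_vocab[lab][int(rng.choice(spec.vocab_per_label, p=zipf))]
                )
            if entity_phrases and rng.random() < spec.entity_rate:
                tokens.extend(entity_phrases[int(rng.integers(len(entity_phrases)))])
        title = " ".join(tokens[:3])
        abstract = " ".join(tokens[3:])
        documents.append(
            Document(id=f"doc{doc_id}", title=title, abstract=abstract,
                     labels=doc_labels)
        )
    return Corpus(documents), embeddings, category_map, entity_lexicon


def generate_all(spec: SyntheticSpec):
    """Convenience wrapper returning every artifact at once.

    Returns ``(corpus, word_embeddings, label_embeddings, category_map,
    entity_lexicon, planted_partition)``.
    """
    labels, label_embeddings, partition = generate_label_space(spec)
    corpus, word_embeddings, category_map, entity_lexicon = generate_corpus(
        spec, labels, partition
    )
    return corpus, word_embeddings, label_embeddings, category_map, entity_lexicon, partition
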