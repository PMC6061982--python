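"""Category distributions and entity meta-features.

Three row-stochastic matrices relate the corpus vocabulary, the document
classes and an external category vocabulary: P1 (word x class), P2
(word x category) and P3 (category x class).  P1 and P3 are counted from
the corpus; P2 is estimated per word row by simplex-constrained least
squares against ``P1 ~= P2 @ P3``, with anchor words (those listed in the
category map) fixed to a uniform distribution over their listed categories.

The entity feature is a bag-of-entity-class count vector pushed through a
seeded random projection with unit-norm columns so that its length matches
the convolutional feature vector it is fused with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CategoryDistributions",
    "EntityAnnotation",
    "build_word_class_distribution",
    "build_category_class_distribution",
    "estimate_word_categories",
    "tag_entities",
    "entity_feature",
]


@dataclass
class CategoryDistributions:
    P1: np.ndarray  # n words x m classes
    P2: np.ndarray  # n words x t categories
    P3: np.ndarray  # t categories x m classes
    word_index: list[str]
    class_index: list[str]
    category_index: list[str]


@dataclass
class EntityAnnotation:
    document_id: str
    #: (start, end) half-open token-index spans with their entity class
    spans: list[tuple[int, int, str]] = field(default_factory=list)


def build_word_class_distribution(corpus) -> tuple[np.ndarray, list[str], list[str]]:
    """P1: row-normalized counts of each word in documents of each class.

    Multi-label documents contribute every occurrence to every class they
    bear.  Returns ``(P1, word_index, class_index)``.
    """
    class_index = corpus.label_vocabulary
    cpos = {c: j for j, c in enumerate(class_index)}
    word_index: list[str] = []
    wpos: dict[str, int] = {}
    rows: list[np.ndarray] = []
    m = len(class_index)
    for doc in corpus:
        cols = [cpos[lab] for lab in doc.labels]
        for tok in doc.tokens:
            i = wpos.get(tok)
            if i is None:
                i = wpos[tok] = len(word_index)
                word_index.append(tok)
                rows.append(np.zeros(m))
            for j in cols:
                rows[i][j] += 1
    P1 = np.vstack(rows) if rows else np.zeros((0, m))
    totals = P1.sum(axis=1, keepdims=True)
    P1 = np.divide(P1, totals, out=P1, where=totals > 0)
    return P1, word_index, class_index


def build_category_class_distribution(
    corpus, category_map: Mapping[str, Sequence[str]]
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """P3: row-normalized counts of category anchor-word occurrences per class.

    A category whose anchor words never occur gets a uniform row and is
    returned in the ``empty`` report list.  Returns
    ``(P3, category_index, class_index, empty)``.
    """
    class_index = corpus.label_vocabulary
    cpos = {c: j for j, c in enumerate(class_index)}
    category_index = sorted({c for cats in category_map.values() for c in cats})
    kpos = {c: k for k, c in enumerate(category_index)}
    m = len(class_index)
    P3 = np.zeros((len(category_index), m))
    for doc in corpus:
        cols = [cpos[lab] for lab in doc.labels]
        for tok in doc.tokens:
            for cat in category_map.get(tok, ()):
                for j in cols:
                    P3[kpos[cat], j] += 1
    empty = [category_index[k] for k in range(len(category_index)) if P3[k].sum() == 0]
    totals = P3.sum(axis=1, keepdims=True)
    P3 = np.divide(P3, totals, out=P3, where=totals > 0)
    if m:
        for cat in empty:
            P3[kpos[cat]] = 1.0 / m
    return P3, category_index, class_index, empty


def _simplex_lsq(P3: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """argmin_x ||x @ P3 - p1||^2 over the probability simplex."""
    t = P3.shape[0]
    x0, *_ = np.linalg.lstsq(P3.T, p1, rcond=None)
    if x0.min() >= -1e-9 and abs(x0.sum() - 1.0) <= 1e-7:
        x0 = np.clip(x0, 0.0, None)
        return x0 / x0.sum()
    # fall back to a constrained solve from a feasible start
    start = np.clip(x0, 0.0, None)
    start = start / start.sum() if start.sum() > 0 else np.full(t, 1.0 / t)

    def objective(x):
        r = x @ P3 - p1
        return float(r @ r)

    def gradient(x):
        return 2.0 * ((x @ P3 - p1) @ P3.T)

    res = minimize(
        objective,
        start,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * t,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, None)
    return x / x.sum()


def estimate_word_categories(
    P1: np.ndarray,
    P3: np.ndarray,
    word_index: Sequence[str],
    category_index: Sequence[str],
    category_map: Mapping[str, Sequence[str]] | None = None,
) -> np.ndarray:
    """Estimate P2 (word x category) from P1 and P3.

    Anchor words — those present in ``category_map`` — are assigned a
    uniform distribution over their listed categories; every other row is
    the simplex-constrained least-squares fit of ``P1_i ~= P2_i @ P3``.
    """
    t, m = P3.shape
    if t > m:
        warnings.warn(
            f"{t} categories > {m} classes: P2 is underdetermined", stacklevel=2
        )
    category_map = category_map or {}
    kpos = {c: k for k, c in enumerate(category_index)}
    P2 = np.zeros((P1.shape[0], t))
    for i, word in enumerate(word_index):
        listed = [c for c in category_map.get(word, ()) if c in kpos]
        if listed:
            for c in listed:
                P2[i, kpos[c]] = 1.0 / len(listed)
        else:
            P2[i] = _simplex_lsq(P3, P1[i])
    return P2


def tag_entities(
    tokens: Sequence[str], entity_lexicon: Mapping[tuple[str, ...], str],
    document_id: str = "",
) -> EntityAnnotation:
    """Greedy longest-match left-to-right lexicon tagging (non-overlapping)."""
    if not entity_lexicon:
        return EntityAnnotation(document_id, [])
    max_len = max(len(phrase) for phrase in entity_lexicon)
    spans: list[tuple[int, int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            phrase = tuple(tokens[i : i + length])
            cls = entity_lexicon.get(phrase)
            if cls is not None:
                spans.append((i, i + length, cls))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return EntityAnnotation(document_id, spans)


def entity_feature(
    annotation: EntityAnnotation,
    entity_class_vocabulary: Sequence[str],
    target_dim: int,
    seed: int = 0,
) -> np.ndarray:
    """Global entity feature vector of length ``target_dim``.

    Entity-class counts are mapped through a fixed seeded Gaussian random
    projection whose columns have unit norm, then scaled to unit max-abs.
    Documents with no entities yield the zero vector.
    """
    vocab = list(entity_class_vocabulary)
    counts = np.zeros(len(vocab))
    pos = {c: i for i, c in enumerate(vocab)}
    for _, _, cls in annotation.spans:
        if cls in pos:
            counts[pos[cls]] += 1
    if counts.sum() == 0 or not vocab:
        return np.zeros(target_dim)
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((target_dim, len(vocab)))
    norms = np.linalg.norm(projection, axis=0)
    projection = projection / norms
    y_e = projection @ counts
    peak = np.abs(y_e).max()
    if peak > 0:
        y_e = y_e / peak
    return y_e
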