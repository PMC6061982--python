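"""Fixed-length document encoding from word embeddings.

Every document is mapped to exactly ``L`` token positions (``L`` = floor of
the corpus mean token count): short documents are padded with the reserved
``UNKNOWN`` token, long documents keep only the occurrences of their most
frequent words.  Each surviving token is then widened to four words — the
token itself plus up to three extension words drawn from its entity class
and its category-map entries — and each of the four is replaced by its
``d``-dimensional embedding, giving an ``L x 4d`` matrix per document.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, EmbeddingTable, UNKNOWN

__all__ = [
    "DocumentMatrix",
    "average_length",
    "fit_to_length",
    "enrich_token",
    "embed_document",
]

#: number of words per position after enrichment (token + 3 extensions)
WORDS_PER_POSITION = 4


@dataclass
class DocumentMatrix:
    matrix: np.ndarray  # shape (L, 4*d)
    document_id: str = ""


def average_length(corpus: Corpus) -> int:
    """Floor of the mean token count over the corpus, at least 1."""
    if len(corpus) == 0:
        raise ValueError("cannot take average length of an empty corpus")
    mean = sum(len(doc.tokens) for doc in corpus) / len(corpus)
    return max(1, int(mean))


def fit_to_length(
    tokens: Sequence[str], L: int, return_indices: bool = False
) -> list[str] | tuple[list[str], list[int | None]]:
    """Force a token sequence to length exactly *L*.

    Shorter sequences are padded with ``UNKNOWN``.  Longer sequences rank
    distinct words by in-document frequency (ties broken by earliest first
    occurrence) and keep whole words in rank order; the first word whose
    occurrences would overflow *L* contributes only its earliest
    occurrences, and lower-ranked words are dropped.  Kept tokens preserve
    their original relative order.

    With ``return_indices=True`` also returns, per output position, the
    index of the token in the original sequence (``None`` for padding).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    tokens = list(tokens)
    indices: list[int | None]
    if len(tokens) <= L:
        out = tokens + [UNKNOWN] * (L - len(tokens))
        indices = list(range(len(tokens))) + [None] * (L - len(tokens))
    else:
        freq = Counter(tokens)
        first = {}
        for i, tok in enumerate(tokens):
            first.setdefault(tok, i)
        ranked = sorted(freq, key=lambda w: (-freq[w], first[w]))
        positions: dict[str, list[int]] = {}
        for i, tok in enumerate(tokens):
            positions.setdefault(tok, []).append(i)
        keep: list[int] = []
        remaining = L
        for word in ranked:
            occ = positions[word]
            if len(occ) <= remaining:
                keep.extend(occ)
                remaining -= len(occ)
            else:
                keep.extend(occ[:remaining])
                remaining = 0
            if remaining == 0:
                break
        keep.sort()
        out = [tokens[i] for i in keep]
        indices = list(keep)
    if return_indices:
        return out, indices
    return out


def enrich_token(
    token: str,
    categories: Sequence[str] = (),
    entity_class: str | None = None,
) -> tuple[str, str, str, str]:
    """Widen a token to (token, x1, x2, x3).

    Extension slots are filled first from the token's entity class (when
    tagged), then from its categories in map order; leftover slots repeat
    the token itself.
    """
    pool: list[str] = []
    if entity_class is not None:
        pool.append(entity_class)
    pool.extend(categories)
    extensions = pool[: WORDS_PER_POSITION - 1]
    while len(extensions) < WORDS_PER_POSITION - 1:
        extensions.append(token)
    return (token, *extensions)


def embed_document(
    tokens: Sequence[str],
    L: int,
    category_map: Mapping[str, Sequence[str]],
    entity_annotation,
    embeddings: EmbeddingTable,
    document_id: str = "",
) -> DocumentMatrix:
    """Full encoding: fit to length, enrich, embed.  Returns an L x 4d matrix.

    ``entity_annotation`` is an :class:`~semindex.meta_features.EntityAnnotation`
    (or ``None``); its spans index the *original* token sequence.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    d = embeddings.dimension
    fitted, src_indices = fit_to_length(tokens, L, return_indices=True)
    entity_by_index: dict[int, str] = {}
    if entity_annotation is not None:
        for start, end, cls in entity_annotation.spans:
            for i in range(start, end):
                entity_by_index[i] = cls
    matrix = np.empty((L, WORDS_PER_POSITION * d))
    for pos, (tok, src) in enumerate(zip(fitted, src_indices)):
        entity_class = entity_by_index.get(src) if src is not None else None
        categories = category_map.get(tok, ())
        words = enrich_token(tok, categories, entity_class)
        for slot, word in enumerate(words):
            matrix[pos, slot * d : (slot + 1) * d] = embeddings.vector(word)
    return DocumentMatrix(matrix=matrix, document_id=document_id)
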