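"""Corpus, embedding-table and mapping-table I/O plus text preprocessing.

File formats
------------
* Corpus: JSON-lines, one object per line with keys ``id`` (str), ``title``
  (str), ``abstract`` (str) and ``labels`` (list of str).
* Embeddings: word2vec text format — header line ``"N d"`` followed by
  space-separated rows ``"word v1 ... vd"``.
* Category map: TSV, column 1 = word, columns 2..k = category terms.
* Entity lexicon: TSV, column 1 = space-joined surface token sequence,
  column 2 = entity class.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stemming import stem

__all__ = [
    "UNKNOWN",
    "Document",
    "Corpus",
    "EmbeddingTable",
    "CorpusFormatError",
    "load_stopwords",
    "preprocess",
    "read_corpus",
    "write_corpus",
    "read_embeddings",
    "write_embeddings",
    "read_category_map",
    "write_category_map",
    "read_entity_lexicon",
    "write_entity_lexicon",
]

#: Reserved token used for padding and out-of-vocabulary lookups.
UNKNOWN = "UNKNOWN"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class CorpusFormatError(ValueError):
    """Raised when an input file does not conform to its documented format."""


@dataclass
class Document:
    id: str
    title: str
    abstract: str
    labels: set[str]
    tokens: list[str] = field(default_factory=list)


@dataclass
class Corpus:
    documents: list[Document]

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise CorpusFormatError("duplicate document ids in corpus")

    @property
    def label_vocabulary(self) -> list[str]:
        seen: set[str] = set()
        for doc in self.documents:
            seen.update(doc.labels)
        return sorted(seen)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


@dataclass
class EmbeddingTable:
    dimension: int
    entries: dict[str, np.ndarray]
    unknown_vector: np.ndarray

    def __post_init__(self) -> None:
        self.unknown_vector = np.asarray(self.unknown_vector, dtype=float)
        if self.unknown_vector.shape != (self.dimension,):
            raise ValueError("unknown_vector length must equal dimension")
        for word, vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for {word!r} has wrong length")
            self.entries[word] = vec

    def vector(self, word: str) -> np.ndarray:
        """Look up *word*, falling back to the unknown vector."""
        return self.entries.get(word, self.unknown_vector)

    def __contains__(self, word: str) -> bool:
        return word in self.entries


def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Load a stopword list (one lowercase word per line).

    With no argument the versioned English list shipped with the package is
    used.
    """
    if path is None:
        text = (
            resources.files("semindex").joinpath("data/stopwords.txt").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w for w in text.split() if w)


def preprocess(
    text: str,
    stopwords: Iterable[str] | None = None,
    stemmer: str = "porter",
) -> list[str]:
    """Tokenize and normalize *text*.

    Lowercases, splits on non-alphanumeric characters (pure-numeric tokens
    are kept), drops stopwords, then stems each surviving token.  Token
    order is preserved.  ``stemmer`` may be ``"porter"`` or ``"none"``.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    else:
        stopwords = frozenset(stopwords)
    if stemmer not in ("porter", "none"):
        raise ValueError(f"unknown stemmer {stemmer!r}")
    tokens = _TOKEN_RE.findall(text.lower())
    kept = [t for t in tokens if t not in stopwords]
    if stemmer == "porter":
        kept = [stem(t) for t in kept]
    return kept


def preprocess_corpus(
    corpus: Corpus,
    stopwords: Iterable[str] | None = None,
    stemmer: str = "porter",
) -> Corpus:
    """Fill ``tokens`` for every document (title first, then abstract)."""
    if stopwords is None:
        stopwords = load_stopwords()
    for doc in corpus:
        doc.tokens = preprocess(
            doc.title + " " + doc.abstract, stopwords, stemmer
        )
    return corpus


# ---------------------------------------------------------------------------
# corpus JSON-lines
# ---------------------------------------------------------------------------

def read_corpus(path: str) -> Corpus:
    documents: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: malformed JSON ({exc.msg})"
                ) from exc
            for key in ("id", "labels"):
                if key not in obj:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: missing required field {key!r}"
                    )
            documents.append(
                Document(
                    id=str(obj["id"]),
                    title=str(obj.get("title", "")),
                    abstract=str(obj.get("abstract", "")),
                    labels=set(map(str, obj["labels"])),
                )
            )
    return Corpus(documents)


def write_corpus(corpus: Corpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(
                json.dumps(
                    {
                        "id": doc.id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "labels": sorted(doc.labels),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# word2vec text format
# ---------------------------------------------------------------------------

def read_embeddings(path: str) -> EmbeddingTable:
    """Read a word2vec-text embedding file.

    A row for the reserved ``UNKNOWN`` token becomes the table's
    ``unknown_vector``; when absent the zero vector is used.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}:1: header must be 'count dim'")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise CorpusFormatError(f"{path}:1: header must be 'count dim'") from exc
        entries: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            entries[parts[0]] = np.array([float(v) for v in parts[1:]])
    if len(entries) != count:
        raise CorpusFormatError(
            f"{path}: header declares {count} rows, found {len(entries)}"
        )
    unknown = entries.pop(UNKNOWN, np.zeros(dim))
    return EmbeddingTable(dimension=dim, entries=entries, unknown_vector=unknown)


def write_embeddings(table: EmbeddingTable, path: str, decimals: int = 6) -> None:
    rows = dict(table.entries)
    if np.any(table.unknown_vector):
        rows[UNKNOWN] = table.unknown_vector
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(rows)} {table.dimension}\n")
        for word in sorted(rows):
            vals = " ".join(f"{v:.{decimals}f}" for v in rows[word])
            fh.write(f"{word} {vals}\n")


# ---------------------------------------------------------------------------
# TSV mapping tables
# ---------------------------------------------------------------------------

def read_category_map(path: str) -> dict[str, list[str]]:
    """word -> ordered list of category terms."""
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: need word + at least one category"
                )
            mapping[cols[0]] = [c for c in cols[1:] if c]
    return mapping


def write_category_map(mapping: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(mapping):
            fh.write(word + "\t" + "\t".join(mapping[word]) + "\n")


def read_entity_lexicon(path: str) -> dict[tuple[str, ...], str]:
    """space-joined token sequence -> entity class."""
    lexicon: dict[tuple[str, ...], str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: need exactly 2 columns (phrase, class)"
                )
            lexicon[tuple(cols[0].split())] = cols[1]
    return lexicon


def write_entity_lexicon(lexicon: Mapping[tuple[str, ...], str], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for phrase in sorted(lexicon):
            fh.write(" ".join(phrase) + "\t" + lexicon[phrase] + "\n")
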