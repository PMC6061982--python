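"""Coarse-to-fine multi-label classification over clustered label embeddings.

Labels are grouped into coarse clusters by k-means on their embedding
vectors.  A coarse head scores cluster membership and, within each
selected cluster, a per-cluster fine head scores the individual labels;
both heads are sigmoid-linear and trained with mean squared error.  A flat
baseline (one independent member / non-member node pair per label) is
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .dbm import sigmoid

__all__ = [
    "CoarsePartition",
    "HierarchyWeights",
    "cluster_labels",
    "coarse_loss",
    "fine_loss",
    "coarse_targets",
    "predict_labels",
    "dbc_predict",
]


@dataclass
class CoarsePartition:
    n_clusters: int
    assignment: dict[str, int]          # label -> cluster id
    centers: np.ndarray                 # (n_clusters, embed dim)

    def members(self, cluster: int) -> list[str]:
        return sorted(l for l, c in self.assignment.items() if c == cluster)


@dataclass
class HierarchyWeights:
    coarse: np.ndarray                  # (C, dim)
    fine: dict[int, np.ndarray]         # cluster -> (n_k, dim)
    fine_labels: dict[int, list[str]]   # cluster -> label order of the rows
    tau_coarse: float = 0.5
    tau_fine: float = 0.5


def cluster_labels(
    label_embeddings: Mapping[str, np.ndarray], C: int, seed: int = 0
) -> CoarsePartition:
    """Deterministic k-means (k-means++ init, Euclidean) over label vectors."""
    labels = sorted(label_embeddings)
    if C < 1:
        raise ValueError("C must be >= 1")
    if C > len(labels):
        raise ValueError(f"C={C} exceeds number of labels ({len(labels)})")
    X = np.vstack([np.asarray(label_embeddings[l], dtype=float) for l in labels])
    km = KMeans(n_clusters=C, init="k-means++", n_init=10, max_iter=100,
                random_state=seed)
    assign = km.fit_predict(X)
    return CoarsePartition(
        n_clusters=C,
        assignment={l: int(c) for l, c in zip(labels, assign)},
        centers=km.cluster_centers_,
    )


def coarse_targets(
    doc_labels: Sequence[set[str]], partition: CoarsePartition
) -> np.ndarray:
    """Binary (N, C) matrix: a document targets every cluster that contains
    one of its labels."""
    out = np.zeros((len(doc_labels), partition.n_clusters))
    for i, labels in enumerate(doc_labels):
        for lab in labels:
            out[i, partition.assignment[lab]] = 1.0
    return out


def _squared_head_loss(x: np.ndarray, w: np.ndarray, y: np.ndarray,
                       denom: float):
    """Shared core: f = sigmoid(x w'), E = (1/denom) sum (f-y)^2."""
    f = sigmoid(x @ w.T)
    diff = f - y
    loss = float((diff * diff).sum() / denom)
    dpre = 2.0 / denom * diff * f * (1.0 - f)
    dw = dpre.T @ x
    dx = dpre @ w
    return f, loss, dw, dx


def coarse_loss(x, w, targets, return_dx: bool = False):
    """Mean squared error of the coarse head, averaged over samples and
    clusters, with its gradient w.r.t. ``w``.

    ``x``: (N, dim) inputs; ``w``: (C, dim); ``targets``: binary (N, C).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    w = np.asarray(w, dtype=float)
    n, C = targets.shape
    if n == 0:
        raise ValueError("need at least one sample")
    _, loss, dw, dx = _squared_head_loss(x, w, targets, float(n * C))
    return (loss, dw, dx) if return_dx else (loss, dw)


def fine_loss(x, w_k, targets, return_dx: bool = False):
    """Per-cluster squared error, normalized by the cluster's label count
    and the sample count; gradients of different clusters are independent.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    w_k = np.asarray(w_k, dtype=float)
    n, n_k = targets.shape
    if n_k == 0:
        raise ValueError("empty cluster")
    _, loss, dw, dx = _squared_head_loss(x, w_k, targets, float(n * n_k))
    return (loss, dw, dx) if return_dx else (loss, dw)


def predict_labels(
    x: np.ndarray,
    partition: CoarsePartition,
    weights: HierarchyWeights,
) -> set[str]:
    """Coarse-to-fine decision for one input vector.

    Clusters with coarse score >= tau_coarse are selected (the argmax
    cluster when none passes); within selected clusters, labels with fine
    score >= tau_fine are emitted; if that union is empty, the single best
    fine label across the selected clusters is returned.  Labels outside
    selected clusters are never returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    coarse_scores = sigmoid(weights.coarse @ x)
    selected = np.flatnonzero(coarse_scores >= weights.tau_coarse)
    if selected.size == 0:
        selected = np.array([int(np.argmax(coarse_scores))])
    out: set[str] = set()
    best_label, best_score = None, -np.inf
    for c in selected:
        w_k = weights.fine[int(c)]
        labels_k = weights.fine_labels[int(c)]
        scores = sigmoid(w_k @ x)
        for lab, s in zip(labels_k, scores):
            if s >= weights.tau_fine:
                out.add(lab)
            if s > best_score:
                best_label, best_score = lab, s
    if not out and best_label is not None:
        out = {best_label}
    return out


def dbc_predict(
    x: np.ndarray, weights: np.ndarray, labels: Sequence[str]
) -> set[str]:
    """Flat baseline decision: every label has a (member, non-member) node
    pair; the label is emitted iff its member node strictly exceeds the
    non-member node (ties excluded).

    ``weights``: (n_labels, 2, dim).
    """
    x = np.asarray(x, dtype=float).ravel()
    scores = sigmoid(weights @ x)  # (n_labels, 2)
    return {lab for lab, (m, nm) in zip(labels, scores) if m > nm}
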