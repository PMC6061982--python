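"""End-to-end orchestration: splitting, training, prediction, evaluation.

Training runs in three phases: (1) encode every document as a fixed-size
matrix and a global entity vector, (2) generatively pretrain the Boltzmann
stack on fused visible vectors (RBM layer-wise, then contrastive steps
with label units), (3) jointly fine-tune the whole stack — classification
heads, Boltzmann machine, fusion matrices and the convolutional network —
by stochastic gradient descent on the coarse + fine squared-error losses.
The deterministic mean-field test path of the Boltzmann machine is used as
the differentiable link between the heads and the lower stack.

Modes: ``bcnn`` (full stack), ``hc`` (heads read the CNN output directly,
Boltzmann machine bypassed) and ``dbc`` (flat per-label member/non-member
baseline on the CNN output).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import dbm as dbm_mod
from .cnn import CNN, CNNConfig
from .corpus_io import (
    Corpus,
    EmbeddingTable,
    load_stopwords,
    preprocess_corpus,
)
from .dbm import DBMParams, sigmoid
from .dse import average_length, embed_document
from .hierarchy import (
    CoarsePartition,
    HierarchyWeights,
    cluster_labels,
    coarse_targets,
    coarse_loss,
    fine_loss,
    dbc_predict,
    predict_labels,
)
from .meta_features import EntityAnnotation, entity_feature, tag_entities
from .metrics import class_counts, macro_metrics, micro_metrics, roc_curve

logger = logging.getLogger("semindex")

__all__ = [
    "RunConfig",
    "Model",
    "split_corpus",
    "cross_validation_folds",
    "train_model",
    "predict_model",
    "evaluate_model",
    "save_model",
    "load_model",
]


@dataclass
class RunConfig:
    mode: str = "bcnn"                # bcnn | hc | dbc
    seed: int = 0
    # CNN
    n_stages: int = 1
    n_kernels: int = 8
    kernel_h: int = 2
    pool_k: int = 2
    n_fc: int = 2
    fc_width: int = 64
    yc_dim: int = 32
    dropout_rate: float = 0.5
    # DBM
    n_visible: int = 32
    n_h1: int = 24
    n_h2: int = 16
    pretrain_epochs: int = 5
    dbm_epochs: int = 5
    lr_pretrain: float = 0.1
    lr_dbm: float = 0.1
    # joint fine-tuning
    warmup_epochs: int = 20           # bcnn only: CNN warm-up through y_c heads
    finetune_epochs: int = 30
    lr_finetune: float = 1.0
    lr_lower_mult: float = 1.0        # extra factor on DBM/fusion/CNN updates
    batch_size: int = 32
    fine_weight: float = 1.0          # weight of the fine losses vs the coarse loss
    init_gain: float = 2.0            # weight-init gain of the Boltzmann stack
    # hierarchy
    n_clusters: int = 2
    tau_coarse: float = 0.5
    tau_fine: float = 0.5
    x_source: str = "scores"          # head input: "scores" (label layer) | "h2" (top hidden)
    # data paths (used by the CLI)
    corpus: str = ""
    embeddings: str = ""
    label_embeddings: str = ""
    category_map: str = ""
    entity_lexicon: str = ""
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("bcnn", "hc", "dbc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.x_source not in ("scores", "h2"):
            raise ValueError(f"unknown x_source {self.x_source!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def cnn_config(self) -> CNNConfig:
        stages = [
            {"h": self.kernel_h, "n_kernels": self.n_kernels, "k": self.pool_k}
            for _ in range(self.n_stages)
        ]
        fc_sizes = [self.fc_width] * (self.n_fc - 1) + [self.yc_dim]
        return CNNConfig(stages=stages, fc_sizes=fc_sizes,
                         dropout_rate=self.dropout_rate)


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

def split_corpus(
    corpus: Corpus, train_fraction: float, seed: int = 0, max_attempts: int = 100
) -> tuple[Corpus, Corpus]:
    """Seeded random split; every label must appear in the training half.

    The split is re-drawn (fresh permutation) up to ``max_attempts`` times
    until label coverage holds; otherwise an error lists the orphan labels.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    all_labels = set(corpus.label_vocabulary)
    orphans: set[str] = set()
    for _ in range(max_attempts):
        order = rng.permutation(n)
        train_docs = [corpus.documents[i] for i in order[:n_train]]
        test_docs = [corpus.documents[i] for i in order[n_train:]]
        covered = set().union(*(d.labels for d in train_docs)) if train_docs else set()
        orphans = all_labels - covered
        if not orphans:
            return Corpus(train_docs), Corpus(test_docs)
    raise ValueError(
        "could not cover all labels in the training split; orphans: "
        + ", ".join(sorted(orphans))
    )


def cross_validation_folds(
    corpus: Corpus, k: int, seed: int = 0
) -> list[Corpus]:
    """Seeded partition into k near-equal disjoint folds covering the corpus."""
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    return [Corpus([corpus.documents[i] for i in fold]) for fold in folds]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class Model:
    config: RunConfig
    cnn: CNN
    dbm: DBMParams | None
    partition: CoarsePartition | None
    hier: HierarchyWeights | None
    dbc_weights: np.ndarray | None
    labels: list[str]
    L: int
    embeddings: EmbeddingTable
    category_map: dict[str, list[str]]
    entity_lexicon: dict[tuple[str, ...], str]
    entity_classes: list[str]
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def _ensure_tokens(corpus: Corpus) -> None:
    if any(not doc.tokens for doc in corpus.documents):
        preprocess_corpus(corpus, load_stopwords())


def _encode_documents(
    corpus: Corpus,
    L: int,
    embeddings: EmbeddingTable,
    category_map,
    entity_lexicon,
    entity_classes: Sequence[str],
    target_dim: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, list[EntityAnnotation]]:
    """Stack document matrices (N, L, 4, d) and entity vectors (N, target_dim)."""
    d = embeddings.dimension
    X = np.empty((len(corpus), L, 4, d))
    Ye = np.empty((len(corpus), target_dim))
    annotations = []
    for i, doc in enumerate(corpus):
        ann = tag_entities(doc.tokens, entity_lexicon, doc.id)
        annotations.append(ann)
        dm = embed_document(doc.tokens, L, category_map, ann, embeddings, doc.id)
        X[i] = dm.matrix.reshape(L, 4, d)
        Ye[i] = entity_feature(ann, entity_classes, target_dim, seed)
    return X, Ye, annotations


def _augment(x: np.ndarray) -> np.ndarray:
    """Append a constant-1 column (bias folded into the head weights)."""
    return np.hstack([x, np.ones((x.shape[0], 1))])


# ---------------------------------------------------------------------------
# differentiable fused Boltzmann test path
# ---------------------------------------------------------------------------

def _fused_predict_forward(yc, ye, p: DBMParams):
    """Mean-field test path from (y_c, y_e) to label scores, with cache."""
    V = sigmoid(yc @ p.C.T + ye @ p.E.T)
    h1 = sigmoid(V @ (2.0 * p.W1))
    h2 = sigmoid(h1 @ p.W2 + p.bias1)
    h1p = sigmoid(V @ p.W1 + h2 @ p.W2.T + p.bias2)
    h2p = sigmoid(h1p @ p.W2 + p.bias3)
    x = sigmoid(h2p @ p.Wlab.T)
    return x, (yc, ye, V, h1, h2, h1p, h2p, x)


def _fused_predict_backward(cache, dx, p: DBMParams, dh2p_extra=None):
    """Hand backprop of :func:`_fused_predict_forward`.

    ``dx`` is the upstream gradient w.r.t. the label scores; an optional
    extra gradient may be injected directly at the top hidden activation
    h2' (used when the classification heads read h2' instead of the label
    layer).  Returns ``(d y_c, grads)`` with grads keyed by parameter name.
    """
    yc, ye, V, h1, h2, h1p, h2p, x = cache

    def sp(s):
        return s * (1.0 - s)

    dg = dx * sp(x)
    gWlab = dg.T @ h2p
    dh2p = dg @ p.Wlab
    if dh2p_extra is not None:
        dh2p = dh2p + dh2p_extra
    df = dh2p * sp(h2p)
    gW2 = h1p.T @ df
    gb3 = df.sum(axis=0)
    dh1p = df @ p.W2.T
    de = dh1p * sp(h1p)
    gW1 = V.T @ de
    gb2 = de.sum(axis=0)
    dh2 = de @ p.W2
    gW2 += de.T @ h2
    dV = de @ p.W1.T
    dc = dh2 * sp(h2)
    gW2 += h1.T @ dc
    gb1 = dc.sum(axis=0)
    dh1 = dc @ p.W2.T
    db = dh1 * sp(h1)
    gW1 += 2.0 * (V.T @ db)
    dV += 2.0 * (db @ p.W1.T)
    da = dV * sp(V)
    gC = da.T @ yc
    gE = da.T @ ye
    dyc = da @ p.C
    grads = {"C": gC, "E": gE, "W1": gW1, "W2": gW2, "Wlab": gWlab,
             "bias1": gb1, "bias2": gb2, "bias3": gb3}
    return dyc, grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(
    corpus: Corpus,
    word_embeddings: EmbeddingTable,
    label_embeddings: dict[str, np.ndarray],
    category_map: dict[str, list[str]],
    entity_lexicon: dict[tuple[str, ...], str],
    config: RunConfig,
) -> Model:
    """Train a model in the configured mode on a preprocessed corpus."""
    _ensure_tokens(corpus)
    labels = corpus.label_vocabulary
    missing = [l for l in labels if l not in label_embeddings]
    if missing and config.mode != "dbc":
        raise ValueError(
            "label embeddings missing for: " + ", ".join(sorted(missing))
        )
    rng = np.random.default_rng(config.seed)

    L = average_length(corpus)
    cnn = CNN(config.cnn_config(), L, word_embeddings.dimension, seed=config.seed)
    entity_classes = sorted(set(entity_lexicon.values()))
    X, Ye, _ = _encode_documents(
        corpus, L, word_embeddings, category_map, entity_lexicon,
        entity_classes, cnn.output_dim, config.seed,
    )
    n = len(corpus)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    Tar = np.zeros((n, len(labels)))
    for i, doc in enumerate(corpus):
        for lab in doc.labels:
            Tar[i, lab_index[lab]] = 1.0

    partition = None
    hier = None
    dbc_w = None
    dbm_params = None
    history: list[dict] = []

    if config.mode != "dbc":
        C = min(config.n_clusters, len(labels))
        partition = cluster_labels(
            {l: label_embeddings[l] for l in labels}, C, seed=config.seed
        )
        Yc_coarse = coarse_targets([doc.labels for doc in corpus], partition)
        fine_labels = {c: partition.members(c) for c in range(C)}
        fine_targets = {
            c: Tar[:, [lab_index[l] for l in fine_labels[c]]]
            for c in range(C)
        }

    def make_heads(dim: int):
        """Fresh seeded head weights for an input of width ``dim`` (+bias)."""
        if config.mode == "dbc":
            return {"dbc": rng.normal(0.0, 0.1, (len(labels), 2, dim + 1))}
        return {
            "coarse": rng.normal(0.0, 0.1, (partition.n_clusters, dim + 1)),
            "fine": {
                c: rng.normal(0.0, 0.1, (len(fine_labels[c]), dim + 1))
                for c in range(partition.n_clusters)
            },
        }

    def sgd_epochs(epochs: int, heads: dict, use_dbm: bool, phase: str):
        """Joint SGD on the squared-error head losses, backpropagating
        through the Boltzmann test path (when attached) and the CNN."""
        lr = config.lr_finetune
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, config.batch_size):
                idx = order[s : s + config.batch_size]
                yc = cnn.forward(X[idx], train=config.dropout_rate > 0, rng=rng)
                if use_dbm:
                    scores, cache = _fused_predict_forward(yc, Ye[idx], dbm_params)
                    x = scores if config.x_source == "scores" else cache[6]
                else:
                    x = yc
                xa = _augment(x)
                dx = np.zeros_like(xa)
                batch_loss = 0.0
                if config.mode == "dbc":
                    flat_w = heads["dbc"].reshape(-1, xa.shape[1])
                    member = Tar[idx]
                    targets = np.empty((len(idx), 2 * len(labels)))
                    targets[:, 0::2] = member
                    targets[:, 1::2] = 1.0 - member
                    f = sigmoid(xa @ flat_w.T)
                    diff = f - targets
                    denom = float(len(idx) * targets.shape[1])
                    batch_loss += float((diff * diff).sum() / denom)
                    dpre = 2.0 / denom * diff * f * (1.0 - f)
                    gw = dpre.T @ xa
                    dx += dpre @ flat_w
                    flat_w -= lr * gw
                else:
                    loss_c, dw_c, dx_c = coarse_loss(
                        xa, heads["coarse"], Yc_coarse[idx], return_dx=True
                    )
                    batch_loss += loss_c
                    dx += dx_c
                    for c in range(partition.n_clusters):
                        loss_f, dw_f, dx_f = fine_loss(
                            xa, heads["fine"][c], fine_targets[c][idx],
                            return_dx=True,
                        )
                        batch_loss += config.fine_weight * loss_f
                        dx += config.fine_weight * dx_f
                        heads["fine"][c] -= lr * config.fine_weight * dw_f
                    heads["coarse"] -= lr * dw_c
                dx_core = dx[:, :-1]
                lr_low = lr * config.lr_lower_mult
                if use_dbm:
                    if config.x_source == "scores":
                        dyc, grads = _fused_predict_backward(
                            cache, dx_core, dbm_params
                        )
                    else:
                        dyc, grads = _fused_predict_backward(
                            cache, np.zeros_like(scores), dbm_params,
                            dh2p_extra=dx_core,
                        )
                    for name, g in grads.items():
                        getattr(dbm_params, name)[...] -= lr_low * g
                else:
                    dyc = dx_core
                cnn.backward(dyc)
                cnn.sgd_step(lr_low)
                epoch_loss += batch_loss * len(idx)
            history.append({"phase": phase, "epoch": epoch,
                            "loss": epoch_loss / n})
            logger.info("%s epoch %d loss %.6f", phase, epoch, epoch_loss / n)

    if config.mode == "bcnn":
        # phase 1 — warm up the CNN through temporary heads on y_c so the
        # Boltzmann machine sees informative visible vectors
        warm_heads = make_heads(cnn.output_dim)
        sgd_epochs(config.warmup_epochs, warm_heads, use_dbm=False,
                   phase="warmup")
        # phase 2 — generative pretraining + contrastive label training
        dbm_params = dbm_mod.init_params(
            config.n_visible, config.n_h1, config.n_h2, len(labels),
            cnn.output_dim, cnn.output_dim, seed=config.seed,
            gain=config.init_gain,
        )
        yc0 = cnn.forward(X)
        V0 = dbm_mod.fuse_inputs(yc0, Ye, dbm_params)
        dbm_mod.pretrain(V0, dbm_params, config.pretrain_epochs,
                         config.lr_pretrain, config.batch_size, config.seed)
        for epoch in range(config.dbm_epochs):
            order = rng.permutation(n)
            errs = []
            for s in range(0, n, config.batch_size):
                idx = order[s : s + config.batch_size]
                _, (ev, _) = dbm_mod.train_step(
                    V0[idx], Tar[idx], dbm_params, config.lr_dbm
                )
                errs.append(ev)
            history.append({"phase": "dbm", "epoch": epoch,
                            "recon_error": float(np.mean(errs))})
        # phase 3 — joint fine-tuning of heads, DBM, fusion and CNN
        head_in = len(labels) if config.x_source == "scores" else config.n_h2
        heads = make_heads(head_in)
        sgd_epochs(config.finetune_epochs, heads, use_dbm=True,
                   phase="finetune")
    else:
        heads = make_heads(cnn.output_dim)
        sgd_epochs(config.finetune_epochs, heads, use_dbm=False,
                   phase="finetune")

    if config.mode == "dbc":
        dbc_w = heads["dbc"]
    else:
        w_coarse, w_fine = heads["coarse"], heads["fine"]
        hier = HierarchyWeights(
            coarse=w_coarse, fine=w_fine, fine_labels=fine_labels,
            tau_coarse=config.tau_coarse, tau_fine=config.tau_fine,
        )
    return Model(
        config=config, cnn=cnn, dbm=dbm_params, partition=partition,
        hier=hier, dbc_weights=dbc_w, labels=labels, L=L,
        embeddings=word_embeddings, category_map=dict(category_map),
        entity_lexicon=dict(entity_lexicon), entity_classes=entity_classes,
        history=history,
    )


# ---------------------------------------------------------------------------
# prediction / evaluation
# ---------------------------------------------------------------------------

def _model_scores(model: Model, corpus: Corpus) -> np.ndarray:
    """Per-document score vector feeding the decision heads (with bias col)."""
    _ensure_tokens(corpus)
    X, Ye, _ = _encode_documents(
        corpus, model.L, model.embeddings, model.category_map,
        model.entity_lexicon, model.entity_classes,
        model.cnn.output_dim, model.config.seed,
    )
    yc = model.cnn.forward(X)
    if model.config.mode == "bcnn":
        scores, cache = _fused_predict_forward(yc, Ye, model.dbm)
        x = scores if model.config.x_source == "scores" else cache[6]
    else:
        x = yc
    return _augment(x)


def predict_model(
    model: Model, corpus: Corpus, return_scores: bool = False
):
    """Predicted label sets for every document (optionally with per-label
    scores in ``model.labels`` order)."""
    Xa = _model_scores(model, corpus)
    predictions: list[set[str]] = []
    score_rows = np.zeros((len(corpus), len(model.labels)))
    lab_index = {lab: i for i, lab in enumerate(model.labels)}
    for i in range(Xa.shape[0]):
        x = Xa[i]
        if model.config.mode == "dbc":
            flat = sigmoid(model.dbc_weights @ x)  # (n_labels, 2)
            predictions.append(
                {lab for lab, (m, nm) in zip(model.labels, flat) if m > nm}
            )
            score_rows[i] = flat[:, 0]
        else:
            predictions.append(predict_labels(x, model.partition, model.hier))
            coarse_scores = sigmoid(model.hier.coarse @ x)
            for c in range(model.partition.n_clusters):
                fine_scores = sigmoid(model.hier.fine[c] @ x)
                for lab, s in zip(model.hier.fine_labels[c], fine_scores):
                    score_rows[i, lab_index[lab]] = coarse_scores[c] * s
    if return_scores:
        return predictions, score_rows
    return predictions


def evaluate_model(model: Model, corpus: Corpus) -> dict:
    """All macro/micro metrics plus a micro-averaged ROC when possible."""
    predictions, scores = predict_model(model, corpus, return_scores=True)
    gold = [doc.labels for doc in corpus]
    counts = class_counts(predictions, gold, model.labels)
    report: dict = {"n_documents": len(corpus)}
    report.update(macro_metrics(counts))
    report.update(micro_metrics(counts))
    lab_index = {lab: i for i, lab in enumerate(model.labels)}
    truth = np.zeros_like(scores, dtype=int)
    for i, labs in enumerate(gold):
        for lab in labs:
            if lab in lab_index:
                truth[i, lab_index[lab]] = 1
    flat_truth = truth.ravel()
    if 0 < flat_truth.sum() < flat_truth.size:
        _, fpr, tpr, auc = roc_curve(scores.ravel(), flat_truth)
        report["micro_auc"] = auc
        report["roc"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    return report


# ---------------------------------------------------------------------------
# model archive (single .npz with a JSON manifest)
# ---------------------------------------------------------------------------

def save_model(model: Model, path: str) -> None:
    arrays: dict[str, np.ndarray] = {}
    for key, val in model.cnn.state().items():
        arrays[f"cnn_{key}"] = val
    if model.dbm is not None:
        for name in ("C", "E", "W1", "W2", "Wlab", "bias1", "bias2", "bias3",
                     "visible_bias"):
            arrays[f"dbm_{name}"] = getattr(model.dbm, name)
    if model.hier is not None:
        arrays["hier_coarse"] = model.hier.coarse
        for c, w in model.hier.fine.items():
            arrays[f"hier_fine_{c}"] = w
        arrays["partition_centers"] = model.partition.centers
    if model.dbc_weights is not None:
        arrays["dbc_weights"] = model.dbc_weights
    emb_words = sorted(model.embeddings.entries)
    arrays["embedding_matrix"] = np.vstack(
        [model.embeddings.entries[w] for w in emb_words]
    ) if emb_words else np.zeros((0, model.embeddings.dimension))
    arrays["embedding_unknown"] = model.embeddings.unknown_vector
    manifest = {
        "config": asdict(model.config),
        "labels": model.labels,
        "L": model.L,
        "embedding_words": emb_words,
        "embedding_dim": model.embeddings.dimension,
        "category_map": model.category_map,
        "entity_lexicon": {" ".join(k): v for k, v in model.entity_lexicon.items()},
        "entity_classes": model.entity_classes,
        "history": model.history,
    }
    if model.partition is not None:
        manifest["partition"] = {
            "n_clusters": model.partition.n_clusters,
            "assignment": model.partition.assignment,
        }
        manifest["hier"] = {
            "fine_labels": {str(c): v for c, v in model.hier.fine_labels.items()},
            "tau_coarse": model.hier.tau_coarse,
            "tau_fine": model.hier.tau_fine,
        }
    arrays["manifest"] = np.array(json.dumps(manifest))
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str) -> Model:
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["manifest"]))
    config = RunConfig(**manifest["config"])
    emb_words = manifest["embedding_words"]
    matrix = data["embedding_matrix"]
    embeddings = EmbeddingTable(
        dimension=manifest["embedding_dim"],
        entries={w: matrix[i] for i, w in enumerate(emb_words)},
        unknown_vector=data["embedding_unknown"],
    )
    cnn = CNN(config.cnn_config(), manifest["L"], embeddings.dimension,
              seed=config.seed)
    cnn.load_state(
        {k[4:]: data[k] for k in data.files if k.startswith("cnn_")}
    )
    dbm_params = None
    if "dbm_W1" in data.files:
        dbm_params = DBMParams(**{
            name: data[f"dbm_{name}"]
            for name in ("C", "E", "W1", "W2", "Wlab", "bias1", "bias2",
                         "bias3", "visible_bias")
        })
    partition = None
    hier = None
    if "partition" in manifest:
        partition = CoarsePartition(
            n_clusters=manifest["partition"]["n_clusters"],
            assignment={k: int(v) for k, v in
                        manifest["partition"]["assignment"].items()},
            centers=data["partition_centers"],
        )
        fine_labels = {int(c): v for c, v in
                       manifest["hier"]["fine_labels"].items()}
        hier = HierarchyWeights(
            coarse=data["hier_coarse"],
            fine={c: data[f"hier_fine_{c}"] for c in fine_labels},
            fine_labels=fine_labels,
            tau_coarse=manifest["hier"]["tau_coarse"],
            tau_fine=manifest["hier"]["tau_fine"],
        )
    dbc_w = data["dbc_weights"] if "dbc_weights" in data.files else None
    return Model(
        config=config, cnn=cnn, dbm=dbm_params, partition=partition,
        hier=hier, dbc_weights=dbc_w, labels=manifest["labels"],
        L=manifest["L"], embeddings=embeddings,
        category_map=manifest["category_map"],
        entity_lexicon={tuple(k.split()): v
                        for k, v in manifest["entity_lexicon"].items()},
        entity_classes=manifest["entity_classes"],
        history=manifest["history"],
    )
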