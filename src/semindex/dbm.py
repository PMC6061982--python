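"""Two-hidden-layer deep Boltzmann machine with label units.

The visible layer fuses the convolutional feature vector ``y_c`` with the
global entity vector ``y_e`` through weight matrices C and E.  Two hidden
layers h1, h2 sit above it; a label layer connects to h2 through ``Wlab``.
Training follows a contrastive (CD-1 style) reconstruction scheme with
mean-field activations; at test time the bottom-up pass doubles W1 to
compensate for the missing top-down input, h1 is re-sampled from both the
visible layer and h2, and label scores are read out from the re-sampled h2.

All vectors are handled as batches of row vectors ``(N, dim)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import expit

__all__ = [
    "sigmoid",
    "DBMParams",
    "DBMState",
    "init_params",
    "fuse_inputs",
    "energy",
    "up_pass",
    "resample_h1",
    "reconstruct_visible",
    "train_step",
    "pretrain",
    "predict",
]


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), numerically stable for large |x|."""
    return expit(np.asarray(x, dtype=float))


@dataclass
class DBMParams:
    C: np.ndarray        # (|V|, |y_c|) fusion weights for the CNN output
    E: np.ndarray        # (|V|, |y_e|) fusion weights for the entity vector
    W1: np.ndarray       # (|V|, |h1|)
    W2: np.ndarray       # (|h1|, |h2|)
    Wlab: np.ndarray     # (|labels|, |h2|)
    bias1: np.ndarray    # (|h2|,)  feeds the data-phase h2
    bias2: np.ndarray    # (|h1|,)  feeds the re-sampled h1
    bias3: np.ndarray    # (|h2|,)  feeds the reconstruction-phase h2
    visible_bias: np.ndarray  # (|V|,)

    def copy(self) -> "DBMParams":
        return DBMParams(*(np.array(getattr(self, f)) for f in (
            "C", "E", "W1", "W2", "Wlab", "bias1", "bias2", "bias3",
            "visible_bias")))


class DBMState(NamedTuple):
    V: np.ndarray
    h1: np.ndarray
    h2: np.ndarray


def init_params(
    n_visible: int,
    n_h1: int,
    n_h2: int,
    n_labels: int,
    n_yc: int,
    n_ye: int,
    seed: int = 0,
    scale: float = 0.01,
    gain: float | None = None,
) -> DBMParams:
    """Seeded random initialization.

    With ``gain=None`` every matrix is Gaussian with std ``scale``; with a
    gain, each matrix gets std ``gain/sqrt(fan_in)`` — a variance-preserving
    choice that keeps document-level variation alive through the sigmoid
    chain (whose derivative at the origin is 1/4).
    """
    rng = np.random.default_rng(seed)

    def std(fan_in: int) -> float:
        return scale if gain is None else gain / np.sqrt(fan_in)

    return DBMParams(
        C=rng.normal(0.0, std(n_yc), (n_visible, n_yc)),
        E=rng.normal(0.0, std(n_ye), (n_visible, n_ye)),
        W1=rng.normal(0.0, std(n_visible), (n_visible, n_h1)),
        W2=rng.normal(0.0, std(n_h1), (n_h1, n_h2)),
        Wlab=rng.normal(0.0, std(n_h2), (n_labels, n_h2)),
        bias1=np.zeros(n_h2),
        bias2=np.zeros(n_h1),
        bias3=np.zeros(n_h2),
        visible_bias=np.zeros(n_visible),
    )


def _rows(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def fuse_inputs(y_c, y_e, params: DBMParams) -> np.ndarray:
    """V = sigmoid(C y_c + E y_e)."""
    single = np.asarray(y_c).ndim == 1
    y_c, y_e = _rows(y_c), _rows(y_e)
    if y_c.shape[1] != params.C.shape[1] or y_e.shape[1] != params.E.shape[1]:
        raise ValueError("fusion input dimensions do not match C/E")
    out = sigmoid(y_c @ params.C.T + y_e @ params.E.T)
    return out[0] if single else out


def energy(V, h1, h2, tar, params: DBMParams) -> float:
    """-V'W1 h1 - h1'W2 h2 - tar'Wlab h2 (label term dropped when tar is None)."""
    V, h1, h2 = (np.asarray(a, dtype=float).ravel() for a in (V, h1, h2))
    e = -(V @ params.W1 @ h1) - (h1 @ params.W2 @ h2)
    if tar is not None:
        e -= np.asarray(tar, dtype=float).ravel() @ params.Wlab @ h2
    return float(e)


def up_pass(V, tar, params: DBMParams, doubled: bool = False):
    """Bottom-up mean-field pass: h1 then h2 (with the label term if given).

    ``doubled`` doubles W1 — used at test time to compensate for the absent
    top-down input to h1.
    """
    single = np.asarray(V).ndim == 1
    V = _rows(V)
    W1 = 2.0 * params.W1 if doubled else params.W1
    h1 = sigmoid(V @ W1)
    pre2 = h1 @ params.W2 + params.bias1
    if tar is not None:
        pre2 = pre2 + _rows(tar) @ params.Wlab
    h2 = sigmoid(pre2)
    return (h1[0], h2[0]) if single else (h1, h2)


def resample_h1(V, h2, params: DBMParams) -> np.ndarray:
    """h1' = sigmoid(V W1 + h2 W2' + bias2)."""
    single = np.asarray(V).ndim == 1
    out = sigmoid(_rows(V) @ params.W1 + _rows(h2) @ params.W2.T + params.bias2)
    return out[0] if single else out


def reconstruct_visible(h1, params: DBMParams) -> np.ndarray:
    """V' = sigmoid(h1 W1' + visible bias)."""
    single = np.asarray(h1).ndim == 1
    out = sigmoid(_rows(h1) @ params.W1.T + params.visible_bias)
    return out[0] if single else out


def train_step(V, tar, params: DBMParams, learning_rate: float):
    """One contrastive update over a batch.

    Positive phase: h1 from V, h2 from (h1, tar).  Negative phase: V' is
    reconstructed from h1, h1' re-sampled from (V, h2), h2' from (h1', tar)
    with its own bias.  Weights move along the difference of data-driven
    and reconstruction-driven pairwise statistics; biases along activation
    differences.  Returns ``(params, (err_v, err_h1))`` with the mean
    per-sample reconstruction norms.
    """
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    V, tar = _rows(V), _rows(tar)
    n = V.shape[0]
    h1, h2 = up_pass(V, tar, params, doubled=False)
    Vp = reconstruct_visible(h1, params)
    h1p = resample_h1(V, h2, params)
    h2p = sigmoid(h1p @ params.W2 + tar @ params.Wlab + params.bias3)

    lr = learning_rate / n
    params.W1 += lr * (V.T @ h1 - Vp.T @ h1p)
    params.W2 += lr * (h1.T @ h2 - h1p.T @ h2p)
    params.Wlab += lr * (tar.T @ h2 - tar.T @ h2p)
    params.visible_bias += lr * (V - Vp).sum(axis=0)
    params.bias2 += lr * (h1 - h1p).sum(axis=0)
    dh2 = lr * (h2 - h2p).sum(axis=0)
    params.bias1 += dh2
    params.bias3 += dh2

    err_v = float(np.linalg.norm(Vp - V, axis=1).mean())
    err_h1 = float(np.linalg.norm(h1p - h1, axis=1).mean())
    return params, (err_v, err_h1)


def _rbm_cd1(data: np.ndarray, W: np.ndarray, vb: np.ndarray, hb: np.ndarray,
             epochs: int, lr: float, batch_size: int, rng) -> None:
    """In-place CD-1 training of a single (visible, hidden) RBM."""
    n = data.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            v0 = data[order[start : start + batch_size]]
            b = v0.shape[0]
            h0 = sigmoid(v0 @ W + hb)
            v1 = sigmoid(h0 @ W.T + vb)
            h1 = sigmoid(v1 @ W + hb)
            W += lr / b * (v0.T @ h0 - v1.T @ h1)
            vb += lr / b * (v0 - v1).sum(axis=0)
            hb += lr / b * (h0 - h1).sum(axis=0)


def pretrain(
    V_data: np.ndarray,
    params: DBMParams,
    epochs: int,
    learning_rate: float = 0.1,
    batch_size: int = 32,
    seed: int = 0,
) -> DBMParams:
    """Layer-wise CD-1 pretraining of the (V, h1) then (h1, h2) stacks.

    ``epochs=0`` leaves the seeded initialization untouched.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if epochs == 0:
        return params
    rng = np.random.default_rng(seed)
    V_data = _rows(V_data)
    _rbm_cd1(V_data, params.W1, params.visible_bias, params.bias2,
             epochs, learning_rate, batch_size, rng)
    h1_data = sigmoid(V_data @ params.W1 + params.bias2)
    _rbm_cd1(h1_data, params.W2, np.zeros(params.W2.shape[0]), params.bias1,
             epochs, learning_rate, batch_size, rng)
    return params


def predict(V, params: DBMParams) -> np.ndarray:
    """Deterministic mean-field label scores for visible input V.

    Bottom-up with doubled W1 and no label input, then re-sample h1 from
    (V, h2), recompute h2 with the reconstruction bias, and read the label
    scores through Wlab.
    """
    single = np.asarray(V).ndim == 1
    V = _rows(V)
    h1, h2 = up_pass(V, None, params, doubled=True)
    h1p = resample_h1(V, h2, params)
    h2p = sigmoid(h1p @ params.W2 + params.bias3)
    scores = sigmoid(h2p @ params.Wlab.T)
    return scores[0] if single else scores


def rbm_reconstruction_error(V_data: np.ndarray, params: DBMParams) -> float:
    """Mean layer-1 reconstruction norm — used to monitor pretraining."""
    V_data = _rows(V_data)
    h = sigmoid(V_data @ params.W1 + params.bias2)
    Vp = sigmoid(h @ params.W1.T + params.visible_bias)
    return float(np.linalg.norm(Vp - V_data, axis=1).mean())
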