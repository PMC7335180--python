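"""Sparse autoencoders for per-group dimensionality reduction.

Each variable group at each visit is compressed to a low-dimensional module
score by a small autoencoder x~ = s(Wx + b) (encoder) and z = s'(W' x~ + b')
(decoder), trained to minimise the reconstruction MSE plus an l2 weight
penalty.  Sparsity is enforced by dropout on the *input* layer during
training.  Hyperparameters (layer widths, activations, dropout rate, l2) are
selected on a held-out 20% split by reconstruction MSE.

Input importance is quantified by the Gedeon measure: per-neuron normalised
absolute weights P_ij = |w_ij| / sum_p |w_pj|, chained through deeper layers
by summing path products P_ik = sum_r P_ir P_rk.  Influences are
non-negative and sum to one per latent output.

Networks are deliberately tiny (group sizes are tens of features at most),
so training runs on plain numpy with manual backprop and Adam.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np


class AutoencoderError(ValueError):
    pass


def _act(name: str):
    if name == "linear":
        return lambda z: z, lambda z, a: np.ones_like(z)
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)
    if name == "sigmoid":
        f = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return f, lambda z, a: a * (1.0 - a)
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a**2
    raise AutoencoderError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture + training hyperparameters for one group autoencoder.

    ``hidden`` are encoder widths strictly between input dim d and latent
    dim q; the decoder mirrors them.  The reconstruction layer is linear
    (inputs are standardized), all other layers use ``activation``.
    """

    latent: int = 1
    hidden: tuple[int, ...] = ()
    activation: str = "sigmoid"
    decoder_activation: str | None = None  # defaults to `activation`
    dropout: float = 0.2
    l2: float = 1e-4
    lr: float = 1e-2
    epochs: int = 300
    batch_size: int = 32
    optimizer: str = "adam"  # adam | gd
    seed: int = 0

    def __post_init__(self):
        if self.latent < 1:
            raise AutoencoderError("latent dimension must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise AutoencoderError("dropout rate must be in [0, 1)")
        if self.l2 < 0:
            raise AutoencoderError("l2 weight must be >= 0")


class TrainedEncoder:
    """Fitted encoder/decoder weight stacks for one group@visit."""

    def __init__(self, spec: AutoencoderSpec, weights: list[np.ndarray],
                 biases: list[np.ndarray], n_encoder_layers: int,
                 activations: list[str], train_mse: float, val_mse: float,
                 loss_history: list[float]):
        self.spec = spec
        self.weights = weights
        self.biases = biases
        self.n_encoder_layers = n_encoder_layers
        self.activations = activations
        self.train_mse = train_mse
        self.val_mse = val_mse
        self.loss_history = loss_history

    @property
    def d_in(self) -> int:
        return self.weights[0].shape[0]

    @property
    def q(self) -> int:
        return self.weights[self.n_encoder_layers - 1].shape[1]

    def _forward(self, X: np.ndarray, upto: int | None = None) -> np.ndarray:
        a = X
        stop = len(self.weights) if upto is None else upto
        for l in range(stop):
            f, _ = _act(self.activations[l])
            a = f(a @ self.weights[l] + self.biases[l])
        return a

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.d_in:
            raise AutoencoderError(f"expected {self.d_in} columns, got {X.shape[1]}")
        return self._forward(X, upto=self.n_encoder_layers)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, float)
        if Z.shape[1] != self.q:
            raise AutoencoderError(f"expected {self.q} latent columns, got {Z.shape[1]}")
        a = Z
        for l in range(self.n_encoder_layers, len(self.weights)):
            f, _ = _act(self.activations[l])
            a = f(a @ self.weights[l] + self.biases[l])
        return a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))


class IdentityEncoder(TrainedEncoder):
    """Pass-through for single-feature groups: nothing to compress."""

    def __init__(self, d: int = 1):
        self._d = d
        self.spec = None
        self.n_encoder_layers = 0
        self.train_mse = 0.0
        self.val_mse = 0.0
        self.loss_history = []

    @property
    def d_in(self):
        return self._d

    @property
    def q(self):
        return self._d

    def encode(self, X):
        return np.asarray(X, float)

    def decode(self, Z):
        return np.asarray(Z, float)


def _init_layers(widths: list[int], rng: np.random.Generator):
    Ws, bs = [], []
    for din, dout in zip(widths, widths[1:]):
        scale = math.sqrt(2.0 / (din + dout))  # Glorot
        Ws.append(rng.normal(0.0, scale, size=(din, dout)))
        bs.append(np.zeros(dout))
    return Ws, bs


def _train_one(X: np.ndarray, spec: AutoencoderSpec) -> TrainedEncoder:
    n, d = X.shape
    enc_widths = [d, *spec.hidden, spec.latent]
    dec_widths = [spec.latent, *reversed(spec.hidden), d]
    widths = enc_widths + dec_widths[1:]
    n_enc = len(enc_widths) - 1
    dec_act = spec.decoder_activation or spec.activation
    activations = [spec.activation] * n_enc \
        + [dec_act] * (len(dec_widths) - 2) + ["linear"]

    rng = np.random.default_rng(spec.seed)
    Ws, bs = _init_layers(widths, rng)
    mW = [np.zeros_like(w) for w in Ws]
    vW = [np.zeros_like(w) for w in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    loss_history: list[float] = []

    def full_loss():
        enc = TrainedEncoder(spec, Ws, bs, n_enc, activations, 0.0, 0.0, [])
        rec = enc.reconstruct(X)
        return float(np.mean((rec - X) ** 2))

    bsz = min(spec.batch_size, n)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bsz):
            idx = order[start:start + bsz]
            xb = X[idx]
            if spec.dropout > 0:
                keep = rng.random(xb.shape) >= spec.dropout
                a = xb * keep / (1.0 - spec.dropout)
            else:
                a = xb
            # forward
            acts, zs = [a], []
            for l, (W, b) in enumerate(zip(Ws, bs)):
                z = acts[-1] @ W + b
                f, _ = _act(activations[l])
                zs.append(z)
                acts.append(f(z))
            out = acts[-1]
            m = xb.shape[0]
            delta = 2.0 * (out - xb) / (m * out.shape[1])
            gWs, gbs = [None] * len(Ws), [None] * len(bs)
            for l in range(len(Ws) - 1, -1, -1):
                _, df = _act(activations[l])
                delta = delta * df(zs[l], acts[l + 1])
                gWs[l] = acts[l].T @ delta + 2.0 * spec.l2 * Ws[l]
                gbs[l] = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ Ws[l].T
            t += 1
            for l in range(len(Ws)):
                if spec.optimizer == "adam":
                    mW[l] = beta1 * mW[l] + (1 - beta1) * gWs[l]
                    vW[l] = beta2 * vW[l] + (1 - beta2) * gWs[l] ** 2
                    mb[l] = beta1 * mb[l] + (1 - beta1) * gbs[l]
                    vb[l] = beta2 * vb[l] + (1 - beta2) * gbs[l] ** 2
                    mhW = mW[l] / (1 - beta1**t)
                    vhW = vW[l] / (1 - beta2**t)
                    mhb = mb[l] / (1 - beta1**t)
                    vhb = vb[l] / (1 - beta2**t)
                    Ws[l] -= spec.lr * mhW / (np.sqrt(vhW) + eps)
                    bs[l] -= spec.lr * mhb / (np.sqrt(vhb) + eps)
                elif spec.optimizer == "gd":
                    Ws[l] -= spec.lr * gWs[l]
                    bs[l] -= spec.lr * gbs[l]
                else:
                    raise AutoencoderError(f"unknown optimizer {spec.optimizer!r}")
        loss_history.append(full_loss())

    enc = TrainedEncoder(spec, Ws, bs, n_enc, activations,
                         train_mse=loss_history[-1] if loss_history else full_loss(),
                         val_mse=float("nan"), loss_history=loss_history)
    return enc


def train_group_autoencoder(X: np.ndarray, grid: list[AutoencoderSpec],
                            val_frac: float = 0.2, seed: int = 0) -> TrainedEncoder:
    """Grid-search over specs; return the one with lowest held-out MSE.

    ``X`` must be the fully observed, preprocessed (standardized) matrix of
    one group at one visit.  Single-column inputs return an identity
    pass-through encoder.
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise AutoencoderError("non-finite values in autoencoder input")
    if X.shape[1] == 1:
        return IdentityEncoder(1)
    if not grid:
        raise AutoencoderError("empty hyperparameter grid")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        train_idx = val_idx
    Xtr, Xval = X[train_idx], X[val_idx]

    best: TrainedEncoder | None = None
    for spec in grid:
        enc = _train_one(Xtr, spec)
        rec = enc.reconstruct(Xval)
        enc.val_mse = float(np.mean((rec - Xval) ** 2))
        if best is None or enc.val_mse < best.val_mse:
            best = enc
    return best


def default_grid(q: int = 1, d: int | None = None, epochs: int = 300,
                 seed: int = 0) -> list[AutoencoderSpec]:
    """Default search grid: one- and two-layer encoders x {sigmoid, relu}
    x dropout {0.2, 0.5} x l2 {1e-4, 1e-3}."""
    hiddens: list[tuple[int, ...]] = [()]
    if d is not None and d > 2:
        hiddens.append((max(q + 1, math.ceil(d / 2)),))
    grid = []
    for hid, act, drop, l2 in itertools.product(
            hiddens, ("sigmoid", "relu"), (0.2, 0.5), (1e-4, 1e-3)):
        grid.append(AutoencoderSpec(latent=q, hidden=hid, activation=act,
                                    dropout=drop, l2=l2, epochs=epochs, seed=seed))
    return grid


def gedeon_influence(encoder: TrainedEncoder) -> np.ndarray:
    """Per-input influence on each latent output, Gedeon's measure.

    Returns a (d_in, q) column-stochastic matrix: entry (i, k) is the summed
    product of per-neuron normalised absolute weights over all encoder paths
    from input i to latent unit k.  Biases are ignored.
    """
    if isinstance(encoder, IdentityEncoder):
        return np.eye(encoder.d_in)
    P = None
    for l in range(encoder.n_encoder_layers):
        W = np.abs(encoder.weights[l])
        col = W.sum(axis=0)
        col[col == 0] = 1.0
        Pl = W / col
        P = Pl if P is None else P @ Pl
    return P
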