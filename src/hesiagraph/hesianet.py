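"""Heterogeneous siamese network for drug-disease association scoring.

Two channel networks project the drug embedding ``E_r`` and the disease
embedding ``E_p`` into a unified latent space: ``eps_r = f(E_r)`` and
``eps_p = g(E_p)``. Each channel is a stack of dense layers (default widths
512/256/128/64 on a 1024-dim input) with ReLU activations and dropout (rate
0.2) after every layer. The merged representation is the elementwise absolute
difference ``eps_h = |eps_r - eps_p|``, which a small head (one 32-unit ReLU
layer with dropout, then a single sigmoid unit) turns into an association
probability. A pair is called associated when that probability strictly
exceeds 0.5.

*Heterogeneous* mode gives the two channels independent parameters — drugs
and diseases are different kinds of object and get different projections.
*Homogeneous* mode ties the channels to one shared parameter set, which
forces ``eps_h = 0`` whenever the two inputs coincide.

Training minimizes mean binary cross-entropy plus ``kl_weight`` times a
channel-alignment penalty: the symmetrized Kullback-Leibler divergence
between the softmax-normalized channel outputs, encouraging the two latent
distributions to stay close. Optimization is Adam with callbacks mirroring
common deep-learning practice: early stopping on validation accuracy,
learning-rate reduction on plateau, and restoration of the best-by-
validation-accuracy weights.

Everything (initialization, batch order, dropout masks) is driven by seeded
numpy generators; with a fixed seed training is bit-reproducible. Forward and
backward passes are hand-written and verified against finite differences in
the test suite.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import FeatureBlock, LabelledPair, PairSet
from .embedding import EmbeddingTable

__all__ = [
    "ChannelConfig",
    "ModelConfig",
    "TrainConfig",
    "SiameseModel",
    "init_model",
    "forward",
    "bce_loss",
    "channel_kl",
    "train",
    "predict_pairs",
    "expected_param_count",
    "save_model",
    "load_model",
]

_EPS = 1e-7  # probability clamp inside the cross-entropy


@dataclass(frozen=True)
class ChannelConfig:
    input_dim: int = 1024
    layer_widths: tuple[int, ...] = (512, 256, 128, 64)
    activation: str = "relu"
    dropout_rate: float = 0.2

    def __post_init__(self):
        if any(w <= 0 for w in self.layer_widths) or self.input_dim <= 0:
            raise ValueError("layer widths and input_dim must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    channel: ChannelConfig = field(default_factory=ChannelConfig)
    head_width: int = 32
    weight_mode: str = "heterogeneous"  # or "homogeneous"
    kl_weight: float = 0.1
    kl_scope: str = "all_pairs"  # or "positive_only"

    def __post_init__(self):
        if self.head_width <= 0:
            raise ValueError("head_width must be positive")
        if self.weight_mode not in ("heterogeneous", "homogeneous"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.kl_scope not in ("all_pairs", "positive_only"):
            raise ValueError(f"unknown kl_scope {self.kl_scope!r}")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patiences must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


class _Dense:
    """Fully connected layer with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 2.0):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(gain / n_in)
        self.b = np.zeros(n_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


def _build_channel(cfg: ChannelConfig, rng: np.random.Generator) -> list[_Dense]:
    layers, fan_in = [], cfg.input_dim
    for width in cfg.layer_widths:
        layers.append(_Dense(fan_in, width, rng))
        fan_in = width
    return layers


class SiameseModel:
    """Two channel stacks plus the absolute-difference prediction head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.channel_f = _build_channel(config.channel, rng)
        if config.weight_mode == "homogeneous":
            self.channel_g = self.channel_f  # same objects: tied parameters
        else:
            self.channel_g = _build_channel(config.channel, rng)
        h = config.channel.layer_widths[-1]
        self.head_hidden = _Dense(h, config.head_width, rng)
        self.head_out = _Dense(config.head_width, 1, rng, gain=1.0)

    # -- parameter bookkeeping -------------------------------------------
    def layers(self) -> list[_Dense]:
        """Unique layers (shared channel counted once)."""
        seen, out = set(), []
        for layer in (*self.channel_f, *self.channel_g,
                      self.head_hidden, self.head_out):
            if id(layer) not in seen:
                seen.add(id(layer))
                out.append(layer)
        return out

    def num_params(self) -> int:
        return sum(layer.n_params for layer in self.layers())

    def get_weights(self) -> list[np.ndarray]:
        return [arr.copy() for layer in self.layers() for arr in (layer.W, layer.b)]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [arr for layer in self.layers() for arr in (layer.W, layer.b)]
        if len(flat) != len(weights):
            raise ValueError("weight list shape mismatch")
        for dst, src in zip(flat, weights):
            dst[...] = src

    # -- forward ----------------------------------------------------------
    def _channel_forward(self, layers, X, training, rng, cache):
        p = self.config.channel.dropout_rate
        a = X
        for layer in layers:
            z = a @ layer.W + layer.b
            act = np.maximum(z, 0.0)
            if training and p > 0:
                mask = (rng.random(act.shape) >= p) / (1.0 - p)
                out = act * mask
            else:
                mask = None
                out = act
            cache.append((layer, a, z, mask))
            a = out
        return a

    def forward_batch(self, Xr: np.ndarray, Xp: np.ndarray,
                      training: bool = False,
                      rng: np.random.Generator | None = None,
                      cache: dict | None = None):
        """Score a batch of (drug, disease) vector pairs.

        Returns ``(probs, eps_r, eps_p)``; with ``cache`` supplied the
        intermediates needed for backprop are recorded there.
        """
        Xr = np.atleast_2d(np.asarray(Xr, dtype=np.float64))
        Xp = np.atleast_2d(np.asarray(Xp, dtype=np.float64))
        k = self.config.channel.input_dim
        if Xr.shape[1] != k or Xp.shape[1] != k:
            raise ValueError(
                f"input vectors must have length {k}, got {Xr.shape[1]}/{Xp.shape[1]}")
        if training and rng is None:
            rng = np.random.default_rng(0)
        c = cache if cache is not None else {}
        c["f"], c["g"], c["head"] = [], [], []
        eps_r = self._channel_forward(self.channel_f, Xr, training, rng, c["f"])
        eps_p = self._channel_forward(self.channel_g, Xp, training, rng, c["g"])
        diff = eps_r - eps_p
        habs = np.abs(diff)
        p = self.config.channel.dropout_rate
        z1 = habs @ self.head_hidden.W + self.head_hidden.b
        a1 = np.maximum(z1, 0.0)
        if training and p > 0:
            m1 = (rng.random(a1.shape) >= p) / (1.0 - p)
            a1d = a1 * m1
        else:
            m1 = None
            a1d = a1
        z2 = a1d @ self.head_out.W + self.head_out.b
        probs = 1.0 / (1.0 + np.exp(-z2[:, 0]))
        c["head"] = (diff, habs, z1, m1, a1d)
        c["eps"] = (eps_r, eps_p)
        return probs, eps_r, eps_p


def init_model(config: ModelConfig, seed: int = 0) -> SiameseModel:
    return SiameseModel(config, seed)


def expected_param_count(config: ModelConfig) -> int:
    """Independent layer-summation oracle: sum of (fan_in*fan_out + fan_out)."""
    dims = (config.channel.input_dim, *config.channel.layer_widths)
    channel = sum(i * o + o for i, o in zip(dims[:-1], dims[1:]))
    h = config.channel.layer_widths[-1]
    head = (h * config.head_width + config.head_width) + (config.head_width + 1)
    n_channels = 1 if config.weight_mode == "homogeneous" else 2
    return n_channels * channel + head


def forward(model: SiameseModel, drug_vec: np.ndarray, disease_vec: np.ndarray,
            training: bool = False, rng: np.random.Generator | None = None):
    """Single-pair convenience wrapper: returns ``(prob, eps_r, eps_p)``."""
    probs, eps_r, eps_p = model.forward_batch(
        np.atleast_2d(drug_vec), np.atleast_2d(disease_vec), training, rng)
    return float(probs[0]), eps_r[0], eps_p[0]


def bce_loss(y, yhat) -> float:
    """Binary cross-entropy ``-[y log yhat + (1-y) log(1-yhat)]``.

    ``yhat`` is clamped to ``[1e-7, 1 - 1e-7]`` before the logs (values at
    exactly 0 or 1 are tolerated through the clamp); values outside ``[0, 1]``
    are a domain error.
    """
    y = float(y)
    yhat = float(yhat)
    if not 0.0 <= yhat <= 1.0:
        raise ValueError(f"predicted probability {yhat} outside [0, 1]")
    q = min(max(yhat, _EPS), 1.0 - _EPS)
    return float(-(y * np.log(q) + (1.0 - y) * np.log(1.0 - q)))


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def channel_kl(eps_r: np.ndarray, eps_p: np.ndarray) -> float:
    """Symmetrized KL divergence between softmax-normalized channel outputs.

    ``0.5 * [KL(P||Q) + KL(Q||P)]`` with ``P = softmax(eps_r)`` and
    ``Q = softmax(eps_p)``; non-negative, zero iff the normalized vectors
    coincide, and symmetric in its arguments.
    """
    p = _softmax(np.asarray(eps_r, dtype=np.float64))
    q = _softmax(np.asarray(eps_p, dtype=np.float64))
    return float(0.5 * (np.sum(p * np.log(p / q), axis=-1)
                        + np.sum(q * np.log(q / p), axis=-1)))


def _batch_kl_and_grads(eps_r, eps_p, weights):
    """Weighted sum of per-row symmetrized KL plus gradients wrt eps_r/eps_p."""
    p = _softmax(eps_r)
    q = _softmax(eps_p)
    logs = np.log(p) - np.log(q)
    kl_rows = 0.5 * (np.sum(p * logs, axis=1) - np.sum(q * logs, axis=1))
    total = float(np.sum(kl_rows * weights))
    # dD/dp_i and dD/dq_i, then through the softmax Jacobian.
    gp = 0.5 * (logs + 1.0 - q / p)
    gq = 0.5 * (-logs + 1.0 - p / q)
    d_r = p * (gp - np.sum(p * gp, axis=1, keepdims=True))
    d_p = q * (gq - np.sum(q * gq, axis=1, keepdims=True))
    return total, d_r * weights[:, None], d_p * weights[:, None]


def _loss_and_grads(model: SiameseModel, Xr, Xp, y, training=False,
                    rng=None):
    """Mean composite loss and per-layer parameter gradients for one batch."""
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    cache: dict = {}
    probs, eps_r, eps_p = model.forward_batch(Xr, Xp, training=training,
                                              rng=rng, cache=cache)
    q = np.clip(probs, _EPS, 1.0 - _EPS)
    bce = float(-np.mean(y * np.log(q) + (1.0 - y) * np.log(1.0 - q)))

    lam = model.config.kl_weight
    if lam > 0:
        if model.config.kl_scope == "positive_only":
            n_pos = int(y.sum())
            w = (y / n_pos) if n_pos else np.zeros(n)
        else:
            w = np.full(n, 1.0 / n)
        kl_mean, d_eps_r_kl, d_eps_p_kl = _batch_kl_and_grads(eps_r, eps_p, w)
    else:
        kl_mean, d_eps_r_kl, d_eps_p_kl = 0.0, 0.0, 0.0
    loss = bce + lam * kl_mean

    grads: dict[int, list[np.ndarray]] = {}

    def accumulate(layer, gW, gb):
        slot = grads.setdefault(id(layer), [np.zeros_like(layer.W),
                                            np.zeros_like(layer.b)])
        slot[0] += gW
        slot[1] += gb

    # Head backward. d(bce)/d(logit) = (q - y)/n.
    diff, habs, z1, m1, a1d = cache["head"]
    dz2 = ((q - y) / n)[:, None]
    accumulate(model.head_out, a1d.T @ dz2, dz2.sum(axis=0))
    da1 = dz2 @ model.head_out.W.T
    if m1 is not None:
        da1 = da1 * m1
    dz1 = da1 * (z1 > 0)
    accumulate(model.head_hidden, habs.T @ dz1, dz1.sum(axis=0))
    dhabs = dz1 @ model.head_hidden.W.T
    ddiff = dhabs * np.sign(diff)
    d_eps_r = ddiff + lam * d_eps_r_kl
    d_eps_p = -ddiff + lam * d_eps_p_kl

    def channel_backward(chain, d_out):
        da = d_out
        for layer, a_prev, z, mask in reversed(chain):
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            accumulate(layer, a_prev.T @ dz, dz.sum(axis=0))
            da = dz @ layer.W.T

    channel_backward(cache["f"], d_eps_r)
    channel_backward(cache["g"], d_eps_p)
    return loss, bce, kl_mean, grads


class _Adam:
    def __init__(self, layers: Sequence[_Dense], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {id(l): [np.zeros_like(l.W), np.zeros_like(l.b),
                              np.zeros_like(l.W), np.zeros_like(l.b)]
                      for l in layers}
        self._layers = {id(l): l for l in layers}

    def step(self, grads: dict[int, list[np.ndarray]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for key, layer in self._layers.items():
            if key not in grads:
                continue
            gW, gb = grads[key]
            mW, mb, vW, vb = self.state[key]
            mW *= b1; mW += (1 - b1) * gW
            mb *= b1; mb += (1 - b1) * gb
            vW *= b2; vW += (1 - b2) * gW ** 2
            vb *= b2; vb += (1 - b2) * gb ** 2
            layer.W -= self.lr * (mW / corr1) / (np.sqrt(vW / corr2) + self.eps)
            layer.b -= self.lr * (mb / corr1) / (np.sqrt(vb / corr2) + self.eps)


def _split_block(block: FeatureBlock, k: int) -> tuple[np.ndarray, np.ndarray]:
    if block.X.shape[1] != 2 * k:
        raise ValueError(
            f"feature rows have width {block.X.shape[1]}, expected {2 * k}")
    return block.X[:, :k], block.X[:, k:]


def train(model: SiameseModel, train_block: FeatureBlock,
          val_block: FeatureBlock, tc: TrainConfig):
    """Fit the network; returns ``(model, history)``.

    The monitor is validation accuracy: weights are checkpointed at every
    improvement, the learning rate is halved after ``lr_reduce_patience``
    epochs without one, training stops after ``early_stop_patience`` epochs
    without one, and the best checkpoint is restored at the end. ``history``
    is a DataFrame with one row per epoch.
    """
    if len(train_block) == 0 or len(val_block) == 0:
        raise ValueError("training and validation blocks must be non-empty")
    if len(np.unique(train_block.y)) < 2:
        raise ValueError("training block must contain both classes")
    k = model.config.channel.input_dim
    Xr, Xp = _split_block(train_block, k)
    y = train_block.y.astype(np.float64)
    Xr_val, Xp_val = _split_block(val_block, k)
    y_val = val_block.y.astype(np.float64)

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.layers(), tc.learning_rate)
    best_acc = -np.inf
    best_weights = model.get_weights()
    stall_stop = stall_lr = 0
    rows = []
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            loss, _, _, grads = _loss_and_grads(
                model, Xr[idx], Xp[idx], y[idx], training=True, rng=rng)
            opt.step(grads)
            losses.append(loss)
        train_loss = float(np.mean(losses))
        probs_tr, _, _ = model.forward_batch(Xr, Xp)
        train_acc = float(np.mean((probs_tr > 0.5) == (y == 1)))
        val_loss, _, _, _ = _loss_and_grads(model, Xr_val, Xp_val, y_val)
        probs_val, _, _ = model.forward_batch(Xr_val, Xp_val)
        val_acc = float(np.mean((probs_val > 0.5) == (y_val == 1)))
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "train_acc": train_acc, "val_loss": val_loss,
                     "val_acc": val_acc, "lr": opt.lr})
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            stall_stop = stall_lr = 0
        else:
            stall_stop += 1
            stall_lr += 1
            if stall_lr >= tc.lr_reduce_patience:
                opt.lr *= tc.lr_reduce_factor
                stall_lr = 0
            if stall_stop >= tc.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)


def predict_pairs(model: SiameseModel, pairs: PairSet | Sequence[LabelledPair],
                  table: EmbeddingTable, threshold: float = 0.5
                  ) -> list[tuple[str, str, float, int]]:
    """Score pairs in input order; label 1 iff probability strictly > threshold."""
    seq = pairs.pairs if isinstance(pairs, PairSet) else list(pairs)
    if not seq:
        return []
    Xr = table.lookup_many(f"drug:{p.drug}" for p in seq)
    Xp = table.lookup_many(f"disease:{p.disease}" for p in seq)
    probs, _, _ = model.forward_batch(Xr, Xp)
    return [(p.drug, p.disease, float(prob), int(prob > threshold))
            for p, prob in zip(seq, probs)]


def save_model(model: SiameseModel, dirpath) -> None:
    os.makedirs(dirpath, exist_ok=True)
    cfg = model.config
    meta = {
        "channel": {"input_dim": cfg.channel.input_dim,
                    "layer_widths": list(cfg.channel.layer_widths),
                    "activation": cfg.channel.activation,
                    "dropout_rate": cfg.channel.dropout_rate},
        "head_width": cfg.head_width,
        "weight_mode": cfg.weight_mode,
        "kl_weight": cfg.kl_weight,
        "kl_scope": cfg.kl_scope,
    }
    with open(os.path.join(dirpath, "config.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    arrays = {f"w{i}": arr for i, arr in enumerate(model.get_weights())}
    np.savez(os.path.join(dirpath, "weights.npz"), **arrays)


def load_model(dirpath) -> SiameseModel:
    with open(os.path.join(dirpath, "config.json")) as fh:
        meta = json.load(fh)
    cfg = ModelConfig(
        channel=ChannelConfig(
            input_dim=meta["channel"]["input_dim"],
            layer_widths=tuple(meta["channel"]["layer_widths"]),
            activation=meta["channel"]["activation"],
            dropout_rate=meta["channel"]["dropout_rate"]),
        head_width=meta["head_width"], weight_mode=meta["weight_mode"],
        kl_weight=meta["kl_weight"], kl_scope=meta["kl_scope"])
    model = SiameseModel(cfg, seed=0)
    with np.load(os.path.join(dirpath, "weights.npz")) as data:
        model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return model
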