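"""Convolutional networks for c-VEP decoding, on a minimal CPU engine.

All deep models share one small convolutional trunk operating on a single
trial of shape (channels, time):

    input (Ns, Nt)
      -> temporal average-resampling to 4 samples per code bit (252 for the
         63-bit code), so that two /2 poolings land on one feature bin per bit
      -> spatial convolution, Ns x 1 kernels, 8 filters (collapses channels)
      -> temporal conv 1x11, 16 filters, ReLU, 1x2 max pool, 20% dropout
      -> temporal conv 1x14, 32 filters, ReLU, 1x2 max pool, 30% dropout
      -> flatten (32 x 63 = 2016 features)

Three heads sit on the trunk:

* K-bit reconstruction — dense 2016 -> 63 + sigmoid, trained with MSE
  against the binary stimulation code (RMSE monitored); 127,071 added
  parameters.  Its output feeds the distance decoders.
* 6-class classification — dense 2016 -> 6 + softmax, categorical
  cross-entropy; 12,102 added parameters.
* Siamese similarity — dense 2016 -> 63 embedding on each twin (shared
  weights); similarity = sigmoid(dense(|e1 - e2|)), binary cross-entropy on
  same/different pair labels.  Used either as a single multi-class model or
  as an ensemble of six per-class binary models.

The engine implements exactly the layers above with hand-derived gradients
and a seeded Adam optimizer (additive L2), so training is deterministic
given the seed and runs on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .codes import CodeBank
from .synth import EpochSet

__all__ = [
    "TrunkConfig",
    "TrainConfig",
    "Reconstruction",
    "PairBatch",
    "Sequential",
    "build_trunk",
    "build_kbit_head",
    "build_class_head",
    "build_siamese",
    "trunk_param_count",
    "train_reconstruction",
    "train_classifier",
    "reconstruct",
    "predict_classes",
    "make_pairs",
    "train_siamese",
    "siamese_similarity",
    "siamese_score_multiclass",
    "train_siamese_ensemble",
    "siamese_score_ensemble",
    "save_model",
    "load_model",
]


# ----------------------------------------------------------------- layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Standardize(_Layer):
    """Per-trial, per-channel z-scoring (parameter-free input conditioning).

    EEG amplitudes are tens of microvolts; without rescaling the sigmoid
    and softmax heads start deep in saturation.  The scale factors are
    treated as constants in the backward pass.
    """

    def forward(self, x, train, rng):
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        self._sd = sd
        return (x - mu) / sd

    def backward(self, dy):
        return dy / self._sd


class _Resample(_Layer):
    """Fixed average-resampling of the time axis to ``n_out`` bins."""

    def __init__(self, n_in: int, n_out: int) -> None:
        super().__init__()
        edges = (np.arange(n_out + 1) * n_in) // n_out
        # mapping matrix M (n_out, n_in): row i averages its bin
        M = np.zeros((n_out, n_in))
        for i in range(n_out):
            lo, hi = edges[i], edges[i + 1]
            M[i, lo:hi] = 1.0 / (hi - lo)
        self.M = M

    def forward(self, x, train, rng):
        return np.einsum("bct,ot->bco", x, self.M)

    def backward(self, dy):
        return np.einsum("bco,ot->bct", dy, self.M)


class _SpatialConv(_Layer):
    """Ns x 1 convolution: a learned linear map across channels per sample."""

    def __init__(self, n_in: int, n_filters: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_filters, n_in)) * scale
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return np.einsum("fc,bct->bft", self.W, x) + self.b[None, :, None]

    def backward(self, dy):
        self.grads[0][...] = np.einsum("bft,bct->fc", dy, self._x)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        return np.einsum("fc,bft->bct", self.W, dy)


class _TemporalConv(_Layer):
    """1 x k convolution over the time axis, 'same' padding."""

    def __init__(self, n_in: int, n_filters: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        self.pl = (k - 1) // 2
        scale = np.sqrt(2.0 / (n_in * k))
        self.W = rng.standard_normal((n_filters, n_in * k)) * scale
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        B, C, T = x.shape
        k, pl = self.k, self.pl
        x_pad = np.zeros((B, C, T + k - 1))
        x_pad[:, :, pl : pl + T] = x
        cols = np.empty((B, C, k, T))
        for j in range(k):
            cols[:, :, j, :] = x_pad[:, :, j : j + T]
        self._cols = cols.reshape(B, C * k, T)
        self._shape = (B, C, T)
        y = np.einsum("fi,bit->bft", self.W, self._cols) + self.b[None, :, None]
        return y

    def backward(self, dy):
        B, C, T = self._shape
        k, pl = self.k, self.pl
        self.grads[0][...] = np.einsum("bft,bit->fi", dy, self._cols)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dcols = np.einsum("fi,bft->bit", self.W, dy).reshape(B, C, k, T)
        dx_pad = np.zeros((B, C, T + k - 1))
        for j in range(k):
            dx_pad[:, :, j : j + T] += dcols[:, :, j, :]
        return dx_pad[:, :, pl : pl + T]


class _ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2(_Layer):
    """1 x 2 max pooling (stride 2) along the time axis."""

    def forward(self, x, train, rng):
        B, C, T = x.shape
        if T % 2:
            x = x[:, :, : T - 1]
            T -= 1
        xr = x.reshape(B, C, T // 2, 2)
        self._arg = xr.argmax(axis=-1)
        self._shape = (B, C, T)
        return xr.max(axis=-1)

    def backward(self, dy):
        B, C, T = self._shape
        dx = np.zeros((B, C, T // 2, 2))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=-1)
        return dx.reshape(B, C, T)


class _Dropout(_Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(1.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential:
    """A feed-forward stack with a shared dropout RNG."""

    def __init__(self, layers: Sequence[_Layer], meta: dict | None = None) -> None:
        self.layers = list(layers)
        self.meta = dict(meta or {})

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_params(self, include_bias: bool = True) -> int:
        total = 0
        for layer in self.layers:
            for p in layer.params:
                if p.ndim == 1 and not include_bias:
                    continue
                total += p.size
        return total

    def state(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_state(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.state()
        if len(params) != len(arrays):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            p[...] = np.asarray(a).reshape(p.shape)


# --------------------------------------------------------------- configs


@dataclass(frozen=True)
class TrunkConfig:
    """Architecture of the shared convolutional trunk."""

    spatial_filters: int = 8
    temporal_kernel1: int = 11
    temporal_filters1: int = 16
    dropout1: float = 0.20
    temporal_kernel2: int = 14
    temporal_filters2: int = 32
    dropout2: float = 0.30
    samples_per_bit: int = 4  # resample target = K * samples_per_bit


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, additive L2, per-epoch reshuffling)."""

    lr: float = 1e-3
    l2: float = 1e-4
    epochs: int = 40
    batch: int = 64
    shuffle: bool = True
    seed: int = 0
    loss: str = "mse"  # reconstruction loss: {mse, bce}

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class Reconstruction:
    """Per-trial sigmoid outputs: (n_trials, K) values in [0, 1]."""

    y_hat: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y_hat, dtype=np.float64)
        if y.min() < 0 or y.max() > 1:
            raise ValueError("reconstruction values must lie in [0, 1]")
        object.__setattr__(self, "y_hat", y)

    @property
    def K(self) -> int:
        return int(self.y_hat.shape[1])


@dataclass(frozen=True)
class PairBatch:
    """Left/right trial index pairs with same-class labels (balanced)."""

    left: np.ndarray
    right: np.ndarray
    same_class: np.ndarray


# ------------------------------------------------------------ architectures


def build_trunk(
    config: TrunkConfig = TrunkConfig(),
    n_channels: int = 8,
    n_times: int = 538,
    K: int = 63,
    seed: int = 0,
) -> Sequential:
    """Build the shared convolutional trunk; flattened output 32*K = 2016.

    The time axis is average-resampled to ``K * samples_per_bit`` samples so
    the two /2 poolings leave exactly one feature bin per code bit; with
    ``samples_per_bit`` not divisible by 4 the pooled length would not align
    with K and an error is raised.
    """
    t_resampled = K * config.samples_per_bit
    if (t_resampled // 4) * 4 != t_resampled:
        raise ValueError(
            f"resampled length {t_resampled} must be divisible by 4 "
            "(two 1x2 poolings); choose samples_per_bit divisible by 4"
        )
    rng = np.random.default_rng(seed)
    layers = [
        _Standardize(),
        _Resample(n_times, t_resampled),
        _SpatialConv(n_channels, config.spatial_filters, rng),
        _TemporalConv(config.spatial_filters, config.temporal_filters1,
                      config.temporal_kernel1, rng),
        _ReLU(),
        _MaxPool2(),
        _Dropout(config.dropout1),
        _TemporalConv(config.temporal_filters1, config.temporal_filters2,
                      config.temporal_kernel2, rng),
        _ReLU(),
        _MaxPool2(),
        _Dropout(config.dropout2),
        _Flatten(),
    ]
    feature_len = config.temporal_filters2 * (t_resampled // 4)
    return Sequential(layers, meta={
        "kind": "trunk", "feature_len": feature_len, "K": K,
        "n_channels": n_channels, "n_times": n_times,
    })


def trunk_param_count(trunk: Sequential) -> dict[str, int]:
    """Trunk learnable parameters with and without convolution biases."""
    return {
        "with_bias": trunk.n_params(include_bias=True),
        "without_bias": trunk.n_params(include_bias=False),
    }


def build_kbit_head(trunk: Sequential, seed: int = 1) -> Sequential:
    """Trunk + dense(feature_len -> K) + sigmoid (applied in the loss/forward)."""
    rng = np.random.default_rng(seed)
    dense = _Dense(trunk.meta["feature_len"], trunk.meta["K"], rng)
    net = Sequential(trunk.layers + [dense], meta=dict(trunk.meta))
    net.meta.update(kind="kbit", head_params=dense.W.size + dense.b.size)
    return net


def build_class_head(trunk: Sequential, n_classes: int = 6, seed: int = 1) -> Sequential:
    """Trunk + dense(feature_len -> n_classes); softmax applied at inference."""
    rng = np.random.default_rng(seed)
    dense = _Dense(trunk.meta["feature_len"], n_classes, rng)
    net = Sequential(trunk.layers + [dense], meta=dict(trunk.meta))
    net.meta.update(kind="class", n_classes=n_classes,
                    head_params=dense.W.size + dense.b.size)
    return net


class SiameseNet:
    """Shared-weight twin trunks with a similarity head on |e1 - e2|."""

    def __init__(self, trunk: Sequential, seed: int = 1) -> None:
        rng = np.random.default_rng(seed)
        self.embed = Sequential(
            trunk.layers + [_Dense(trunk.meta["feature_len"], trunk.meta["K"], rng)],
            meta=dict(trunk.meta),
        )
        self.head = _Dense(trunk.meta["K"], 1, rng)
        self.meta = dict(trunk.meta)
        self.meta["kind"] = "siamese"

    def forward_pair(
        self, x1: np.ndarray, x2: np.ndarray,
        train: bool = False, rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        # one concatenated pass through the shared twins keeps a single
        # forward cache, so backward accumulates both twins' gradients
        e = self.embed.forward(np.concatenate([x1, x2]), train, rng)
        n = x1.shape[0]
        self._e1, self._e2 = e[:n], e[n:]
        self._diff = self._e1 - self._e2
        d = np.abs(self._diff)
        z = self.head.forward(d, train, rng)[:, 0]
        return _sigmoid(z)

    def backward_pair(self, dz: np.ndarray) -> None:
        dd = self.head.backward(dz[:, None])
        de1 = dd * np.sign(self._diff)
        self.embed.backward(np.concatenate([de1, -de1]))

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.embed.parameters() + list(zip(self.head.params, self.head.grads))

    def state(self) -> list[np.ndarray]:
        return self.embed.state() + self.head.params

    def set_state(self, arrays: Sequence[np.ndarray]) -> None:
        n = len(self.embed.state())
        self.embed.set_state(arrays[:n])
        for p, a in zip(self.head.params, arrays[n:]):
            p[...] = np.asarray(a).reshape(p.shape)


def build_siamese(trunk: Sequential, seed: int = 1) -> SiameseNet:
    return SiameseNet(trunk, seed=seed)


# ------------------------------------------------------------------ Adam


class _Adam:
    def __init__(self, params: Sequence[tuple[np.ndarray, np.ndarray]],
                 lr: float, l2: float) -> None:
        self.params = list(params)
        self.lr, self.l2 = lr, l2
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            g = g + self.l2 * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
                    np.exp(np.clip(z, -500, 500)) /
                    (1.0 + np.exp(np.clip(z, -500, 500))))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


# -------------------------------------------------------------- training


def _epoch_batches(n: int, batch: int, shuffle: bool,
                   rng: np.random.Generator) -> list[np.ndarray]:
    idx = np.arange(n)
    if shuffle:
        rng.shuffle(idx)
    return [idx[i : i + batch] for i in range(0, n, batch)]


def train_reconstruction(
    net: Sequential,
    train: EpochSet,
    bank: CodeBank,
    val: EpochSet | None = None,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Sequential, list[float]]:
    """Train the K-bit head against each trial's binary code row.

    Loss is MSE between the sigmoid outputs and the 0/1 target bits (the
    monitored metric is RMSE); ``cfg.loss='bce'`` switches to binary
    cross-entropy.  Returns the net and the per-epoch validation RMSE
    (training RMSE when no validation set is given).
    """
    if train.labels.max() > bank.n_classes:
        raise ValueError("label outside code bank")
    targets = bank.codes[train.labels - 1].astype(np.float64)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(net.parameters(), cfg.lr, cfg.l2)
    K = targets.shape[1]
    history: list[float] = []
    for _ in range(cfg.epochs):
        for b in _epoch_batches(train.n_trials, cfg.batch, cfg.shuffle, rng):
            z = net.forward(train.data[b], train=True, rng=rng)
            a = _sigmoid(z)
            t = targets[b]
            if cfg.loss == "bce":
                dz = (a - t) / (len(b) * K)
            else:
                dz = 2.0 * (a - t) * a * (1.0 - a) / (len(b) * K)
            net.backward(dz)
            opt.step()
        monitor = val if val is not None else train
        mon_t = bank.codes[monitor.labels - 1].astype(np.float64)
        pred = reconstruct(net, monitor).y_hat
        history.append(float(np.sqrt(np.mean((pred - mon_t) ** 2))))
    return net, history


def train_classifier(
    net: Sequential,
    train: EpochSet,
    val: EpochSet | None = None,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Sequential, list[float]]:
    """Train the 6-class head with categorical cross-entropy.

    Returns the net and the per-epoch validation accuracy history (fractions).
    """
    n_classes = net.meta["n_classes"]
    if train.labels.max() > n_classes:
        raise ValueError("label outside class head range")
    onehot = np.eye(n_classes)[train.labels - 1]
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(net.parameters(), cfg.lr, cfg.l2)
    history: list[float] = []
    for _ in range(cfg.epochs):
        for b in _epoch_batches(train.n_trials, cfg.batch, cfg.shuffle, rng):
            z = net.forward(train.data[b], train=True, rng=rng)
            p = _softmax(z)
            net.backward((p - onehot[b]) / len(b))
            opt.step()
        monitor = val if val is not None else train
        labels, _ = predict_classes(net, monitor)
        history.append(float(np.mean(labels == monitor.labels)))
    return net, history


def _forward_eval(net: Sequential, data: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [net.forward(data[i : i + batch], train=False)
            for i in range(0, len(data), batch)]
    return np.concatenate(outs)


def reconstruct(net: Sequential, epochs: EpochSet) -> Reconstruction:
    """Sigmoid bit reconstructions for every trial (dropout disabled)."""
    return Reconstruction(_sigmoid(_forward_eval(net, epochs.data)))


def predict_classes(net: Sequential, epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Softmax class probabilities and argmax labels (ties to lowest index)."""
    probs = _softmax(_forward_eval(net, epochs.data))
    return np.argmax(probs, axis=1) + 1, probs


# --------------------------------------------------------------- Siamese


def make_pairs(
    epochs: EpochSet,
    n_pairs: int,
    seed: int = 0,
    class_k: int | None = None,
) -> PairBatch:
    """Sample exactly balanced same/different trial pairs.

    With ``class_k`` set, positives are both-in-class-k pairs and negatives
    pair a class-k trial with a non-k trial (the per-class binary setting);
    otherwise positives share any class.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = epochs.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes to draw negative pairs")
    n_pos = n_pairs // 2
    n_neg = n_pairs - n_pos
    left, right, same = [], [], []
    if class_k is None:
        by_class = {c: np.flatnonzero(labels == c) for c in classes}
        pos_classes = rng.choice(classes, size=n_pos)
        for c in pos_classes:
            i, j = rng.choice(by_class[c], size=2, replace=True)
            left.append(i); right.append(j); same.append(1)
        for _ in range(n_neg):
            c1, c2 = rng.choice(classes, size=2, replace=False)
            left.append(rng.choice(by_class[c1]))
            right.append(rng.choice(by_class[c2]))
            same.append(0)
    else:
        in_k = np.flatnonzero(labels == class_k)
        out_k = np.flatnonzero(labels != class_k)
        if in_k.size == 0 or out_k.size == 0:
            raise ValueError(f"class {class_k} or its complement is empty")
        for _ in range(n_pos):
            i, j = rng.choice(in_k, size=2, replace=True)
            left.append(i); right.append(j); same.append(1)
        for _ in range(n_neg):
            left.append(rng.choice(in_k))
            right.append(rng.choice(out_k))
            same.append(0)
    return PairBatch(
        left=np.array(left), right=np.array(right),
        same_class=np.array(same, dtype=np.float64),
    )


def train_siamese(
    net: SiameseNet,
    epochs: EpochSet,
    cfg: TrainConfig = TrainConfig(epochs=30, batch=256),
    class_k: int | None = None,
    iters_per_epoch: int | None = None,
) -> SiameseNet:
    """Train on freshly sampled balanced pairs, BCE on the similarity output."""
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(net.parameters(), cfg.lr, cfg.l2)
    if iters_per_epoch is None:
        iters_per_epoch = max(1, epochs.n_trials // cfg.batch)
    for _ in range(cfg.epochs):
        for _ in range(iters_per_epoch):
            pairs = make_pairs(epochs, cfg.batch,
                               seed=int(rng.integers(2**31)), class_k=class_k)
            a = net.forward_pair(
                epochs.data[pairs.left], epochs.data[pairs.right],
                train=True, rng=rng,
            )
            dz = (a - pairs.same_class) / pairs.same_class.size
            net.backward_pair(dz)
            opt.step()
    return net


def siamese_similarity(
    net: SiameseNet, x1: np.ndarray, x2: np.ndarray, batch: int = 256
) -> np.ndarray:
    outs = [net.forward_pair(x1[i : i + batch], x2[i : i + batch], train=False)
            for i in range(0, len(x1), batch)]
    return np.concatenate(outs)


def _support_refs(
    support: EpochSet, n_ref: int, seed: int, classes: np.ndarray
) -> dict[int, np.ndarray]:
    rng = np.random.default_rng(seed)
    refs = {}
    for c in classes:
        idx = np.flatnonzero(support.labels == c)
        if idx.size == 0:
            raise ValueError(f"class {c} absent from support set")
        refs[int(c)] = rng.choice(idx, size=min(n_ref, idx.size), replace=False)
    return refs


def siamese_score_multiclass(
    net: SiameseNet,
    test: EpochSet,
    support: EpochSet,
    n_ref: int = 10,
    seed: int = 0,
    n_classes: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Score each test trial against n_ref support trials per class.

    score(trial, c) = mean similarity to the class-c references; labels by
    argmax (ties to lowest index).  Returns (labels, score matrix).
    """
    classes = np.arange(1, n_classes + 1)
    refs = _support_refs(support, n_ref, seed, classes)
    scores = np.empty((test.n_trials, n_classes))
    for c in classes:
        ref_data = support.data[refs[int(c)]]
        for r in range(ref_data.shape[0]):
            rep = np.broadcast_to(ref_data[r], test.data.shape).copy()
            if r == 0:
                acc = siamese_similarity(net, test.data, rep)
            else:
                acc += siamese_similarity(net, test.data, rep)
        scores[:, c - 1] = acc / ref_data.shape[0]
    return np.argmax(scores, axis=1) + 1, scores


def train_siamese_ensemble(
    trunk_factory: Callable[[], Sequential],
    train: EpochSet,
    cfg: TrainConfig = TrainConfig(epochs=30, batch=256),
    n_classes: int = 6,
) -> list[SiameseNet]:
    """Train one binary Siamese model per class (positives within the class)."""
    models = []
    for k in range(1, n_classes + 1):
        net = build_siamese(trunk_factory(), seed=cfg.seed + k)
        train_siamese(net, train, replace(cfg, seed=cfg.seed + k), class_k=k)
        models.append(net)
    return models


def siamese_score_ensemble(
    models: Sequence[SiameseNet],
    test: EpochSet,
    support: EpochSet,
    n_ref: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble scoring: model k scores similarity to class-k references.

    Returns (labels, score matrix, binary decisions at threshold 0.5).
    """
    n_classes = len(models)
    classes = np.arange(1, n_classes + 1)
    refs = _support_refs(support, n_ref, seed, classes)
    scores = np.empty((test.n_trials, n_classes))
    for k, net in zip(classes, models):
        ref_data = support.data[refs[int(k)]]
        acc = np.zeros(test.n_trials)
        for r in range(ref_data.shape[0]):
            rep = np.broadcast_to(ref_data[r], test.data.shape).copy()
            acc += siamese_similarity(net, test.data, rep)
        scores[:, k - 1] = acc / ref_data.shape[0]
    labels = np.argmax(scores, axis=1) + 1
    return labels, scores, (scores >= 0.5).astype(int)


# ---------------------------------------------------------- serialization


def save_model(net: Sequential | SiameseNet, path: str | Path) -> None:
    """Save weights (.npz) with a JSON sidecar describing the architecture."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(net.state())}
    np.savez(path.with_suffix(".npz"), **arrays)
    Path(str(path.with_suffix(".json"))).write_text(json.dumps(net.meta))


def load_model(net: Sequential | SiameseNet, path: str | Path) -> None:
    """Load weights saved by :func:`save_model` into a matching architecture."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as f:
        net.set_state([f[f"p{i}"] for i in range(len(f.files))])
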