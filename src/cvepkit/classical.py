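"""Classical decoding baselines: template correlation, CCA features, BLDA.

Two feature families feed a one-vs-rest Bayesian linear discriminant:

* Correlation features — Pearson correlation of every epoch channel with
  every channel of every class template (class-major ordering), giving
  ``n_classes * n_channels * n_channels`` features (384 under the default
  6-class, 8-channel paradigm).
* CCA features — canonical correlations between the epoch (time x channels)
  and each class template, sorted descending and zero-padded to
  ``n_channels`` slots per class (48 features under the defaults).  Rank
  deficiency (e.g. one redundant electrode) simply yields fewer nonzero
  canonical correlations; the exact-zero padding keeps the length fixed.

BLDA is Bayesian linear regression to ±1 targets whose ridge strength is
set by evidence maximization, one binary model per class; the class with
the highest softmax-normalized discriminant wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from sklearn.linear_model import BayesianRidge

from .synth import EpochSet

__all__ = [
    "TemplateBank",
    "BLDAModel",
    "build_templates",
    "corr_features",
    "cca_features",
    "feature_matrix",
    "canonical_correlations",
    "fit_blda",
    "fit_ovr",
    "predict_ovr",
    "template_correlation_decode",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateBank:
    """Class-conditional channel means: (n_classes, n_channels, n_times)."""

    templates: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.templates.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.templates.shape[1])


def build_templates(train: EpochSet, n_classes: int | None = None) -> TemplateBank:
    """Average training trials per class: one template signal per electrode."""
    if n_classes is None:
        n_classes = int(train.labels.max())
    templates = np.empty((n_classes, train.n_channels, train.n_times))
    for c in range(1, n_classes + 1):
        mask = train.labels == c
        if not mask.any():
            raise ValueError(f"class {c} missing from training data")
        templates[c - 1] = train.data[mask].mean(axis=0)
    return TemplateBank(templates=templates)


def _safe_rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of A with every row of B.

    Zero-variance rows yield zero correlations instead of NaN (logged).
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    bad_a, bad_b = na == 0, nb == 0
    if bad_a.any() or bad_b.any():
        logger.warning("zero-variance series encountered; correlations set to 0")
    na[bad_a] = 1.0
    nb[bad_b] = 1.0
    C = (Ac / na[:, None]) @ (Bc / nb[:, None]).T
    C[bad_a, :] = 0.0
    C[:, bad_b] = 0.0
    return np.clip(C, -1.0, 1.0)


def corr_features(epoch: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Correlation feature vector, class-major then (epoch ch, template ch).

    feature[(c, i, j)] = corr(epoch channel i, template channel j of class c).
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.shape != bank.templates.shape[1:]:
        raise ValueError(
            f"epoch shape {epoch.shape} does not match templates "
            f"{bank.templates.shape[1:]}"
        )
    feats = [
        _safe_rowwise_corr(epoch, bank.templates[c]).ravel()
        for c in range(bank.n_classes)
    ]
    return np.concatenate(feats)


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations of two (time x variables) matrices (QR + SVD).

    Returns min(rank X, rank Y) values in descending order, each in [0, 1].
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if Xc.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    qx, rx, px = sla.qr(Xc, mode="economic", pivoting=True)
    qy, ry, py = sla.qr(Yc, mode="economic", pivoting=True)
    tol_x = np.abs(rx[0, 0]) * max(Xc.shape) * np.finfo(float).eps if rx.size else 0
    tol_y = np.abs(ry[0, 0]) * max(Yc.shape) * np.finfo(float).eps if ry.size else 0
    rank_x = int((np.abs(np.diag(rx)) > tol_x).sum())
    rank_y = int((np.abs(np.diag(ry)) > tol_y).sum())
    if rank_x == 0 or rank_y == 0:
        return np.zeros(0)
    svals = sla.svd(qx[:, :rank_x].T @ qy[:, :rank_y], compute_uv=False)
    return np.clip(svals, 0.0, 1.0)


def cca_features(epoch: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Per class: canonical correlations padded with exact zeros to n_channels."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.shape != bank.templates.shape[1:]:
        raise ValueError("epoch/template shape mismatch")
    ns = bank.n_channels
    out = np.zeros(bank.n_classes * ns)
    for c in range(bank.n_classes):
        rho = canonical_correlations(epoch.T, bank.templates[c].T)
        k = min(rho.size, ns)
        out[c * ns : c * ns + k] = rho[:k]
    return out


def feature_matrix(
    epochs: EpochSet, bank: TemplateBank, kind: str = "corr"
) -> np.ndarray:
    """Stack per-trial features: kind in {'corr', 'cca'}."""
    fn = {"corr": corr_features, "cca": cca_features}[kind]
    return np.stack([fn(epochs.data[i], bank) for i in range(epochs.n_trials)])


@dataclass
class BLDAModel:
    """One binary evidence-maximization discriminant (weights, bias, precisions)."""

    weights: np.ndarray
    bias: float
    alpha_prior: float
    beta_noise: float
    n_iter: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.weights.size:
            raise ValueError(
                f"expected {self.weights.size} features, got {X.shape[1]}"
            )
        return X @ self.weights + self.bias

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "alpha_prior": self.alpha_prior,
                    "beta_noise": self.beta_noise,
                    "n_iter": self.n_iter,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BLDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            alpha_prior=float(d["alpha_prior"]),
            beta_noise=float(d["beta_noise"]),
            n_iter=int(d["n_iter"]),
        )


def fit_blda(X: np.ndarray, y_binary: np.ndarray) -> BLDAModel:
    """Fit one binary BLDA: Bayesian ridge regression to ±1 targets.

    The prior and noise precisions are re-estimated by evidence maximization
    until relative convergence (tol 1e-6) or 200 iterations.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y_binary, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    reg = BayesianRidge(max_iter=200, tol=1e-6, fit_intercept=True)
    reg.fit(X, y)
    return BLDAModel(
        weights=reg.coef_.copy(),
        bias=float(reg.intercept_),
        alpha_prior=float(reg.lambda_),
        beta_noise=float(reg.alpha_),
        n_iter=int(getattr(reg, "n_iter_", 200)),
    )


def fit_ovr(X: np.ndarray, labels: np.ndarray, n_classes: int) -> list[BLDAModel]:
    """One-vs-rest ensemble: an independent BLDA per class."""
    return [
        fit_blda(X, np.where(labels == c, 1.0, -1.0))
        for c in range(1, n_classes + 1)
    ]


def predict_ovr(
    models: Sequence[BLDAModel], X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-normalized one-vs-rest scores; argmax labels, ties to lowest."""
    scores = np.stack([m.decision(X) for m in models], axis=1)
    scores = scores - scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = np.argmax(probs, axis=1) + 1  # argmax takes the first (lowest) max
    return labels, probs


def template_correlation_decode(
    epochs: EpochSet, bank: TemplateBank
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax-correlation decoding against class templates.

    The score of class c is the mean over channels of the Pearson
    correlation between the epoch channel and the class-c template channel.
    Returns (labels, score matrix).
    """
    n = epochs.n_trials
    scores = np.empty((n, bank.n_classes))
    for i in range(n):
        for c in range(bank.n_classes):
            scores[i, c] = np.mean(
                np.diag(_safe_rowwise_corr(epochs.data[i], bank.templates[c]))
            )
    labels = np.argmax(scores, axis=1) + 1
    return labels, scores
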