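"""End-to-end decoding pipelines: the method battery behind the experiments.

Each pipeline wraps one decoding method behind a uniform ``fit(train)`` /
``predict(test)`` / ``scores(test)`` surface so that session-wise CV,
augmentation and the CLI treat all methods identically:

================  ====================================================
corr_blda         correlation features -> one-vs-rest BLDA
cca_blda          CCA features -> one-vs-rest BLDA
cnn_kbit_euclid   K-bit CNN reconstruction -> squared Euclidean decode
cnn_kbit_mahal    ... -> shrinkage-Mahalanobis decode
cnn_kbit_emd      ... -> CDF-form EMD decode
cnn_kbit_cemd     ... -> radius-constrained EMD decode (default R=8)
cnn_class         CNN with a 6-class softmax head
siamese_single    single multi-class Siamese similarity scoring
siamese_ensemble  six per-class binary Siamese models
template_corr     template-correlation baseline (no learning)
================  ====================================================

``scores`` returns a trials x classes matrix; ``higher_is_better`` states
whether argmax (probabilities/similarities) or argmin (distances) decodes
it, which is what test-time shift combination needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import classical, decode, nets
from .augment import AugmentConfig, combine_test, expand_train
from .codes import CodeBank, build_code_bank
from .synth import EpochSet

__all__ = [
    "METHODS",
    "make_pipeline",
    "AugmentedPipeline",
    "TemplateCorrPipeline",
    "BLDAPipeline",
    "CnnKbitPipeline",
    "CnnClassPipeline",
    "SiameseSinglePipeline",
    "SiameseEnsemblePipeline",
]


class TemplateCorrPipeline:
    """Argmax channel-wise correlation with class-mean templates."""

    higher_is_better = True

    def __init__(self, n_classes: int = 6) -> None:
        self.n_classes = n_classes

    def fit(self, train: EpochSet) -> "TemplateCorrPipeline":
        self.templates_ = classical.build_templates(train, self.n_classes)
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        _, s = classical.template_correlation_decode(test, self.templates_)
        return s

    def predict(self, test: EpochSet) -> np.ndarray:
        labels, _ = classical.template_correlation_decode(test, self.templates_)
        return labels


class BLDAPipeline:
    """Correlation or CCA features into a one-vs-rest BLDA ensemble."""

    higher_is_better = True

    def __init__(self, kind: str = "corr", n_classes: int = 6) -> None:
        if kind not in ("corr", "cca"):
            raise ValueError("kind must be 'corr' or 'cca'")
        self.kind = kind
        self.n_classes = n_classes

    def fit(self, train: EpochSet) -> "BLDAPipeline":
        self.templates_ = classical.build_templates(train, self.n_classes)
        X = classical.feature_matrix(train, self.templates_, self.kind)
        self.models_ = classical.fit_ovr(X, train.labels, self.n_classes)
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        X = classical.feature_matrix(test, self.templates_, self.kind)
        _, probs = classical.predict_ovr(self.models_, X)
        return probs

    def predict(self, test: EpochSet) -> np.ndarray:
        X = classical.feature_matrix(test, self.templates_, self.kind)
        labels, _ = classical.predict_ovr(self.models_, X)
        return labels


@dataclass
class CnnKbitPipeline:
    """K-bit reconstruction CNN with a distance decoder on its outputs."""

    metric: str = "euclid"  # {euclid, mahal, emd, cemd}
    R: int = 8
    bank: CodeBank | None = None
    train_cfg: nets.TrainConfig = field(
        default_factory=lambda: nets.TrainConfig(epochs=40, batch=64)
    )
    higher_is_better = False

    def __post_init__(self) -> None:
        if self.metric not in ("euclid", "mahal", "emd", "cemd"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.bank is None:
            self.bank = build_code_bank()

    def fit(self, train: EpochSet) -> "CnnKbitPipeline":
        trunk = nets.build_trunk(
            n_channels=train.n_channels, n_times=train.n_times,
            K=self.bank.K, seed=self.train_cfg.seed,
        )
        net = nets.build_kbit_head(trunk, seed=self.train_cfg.seed + 1)
        self.net_, self.history_ = nets.train_reconstruction(
            net, train, self.bank, cfg=self.train_cfg
        )
        # covariance source for Mahalanobis: training-set reconstructions,
        # so the test fold never influences the metric
        self.train_recon_ = nets.reconstruct(self.net_, train)
        return self

    def _decode(self, test: EpochSet):
        recon = nets.reconstruct(self.net_, test)
        if self.metric == "euclid":
            return decode.euclidean_decode(recon, self.bank)
        if self.metric == "mahal":
            return decode.mahalanobis_decode(
                recon, self.bank, cov_source=self.train_recon_
            )
        if self.metric == "emd":
            return decode.emd_decode(recon, self.bank)
        return decode.cemd_decode(recon, self.bank, R=self.R)

    def scores(self, test: EpochSet) -> np.ndarray:
        dm, _ = self._decode(test)
        return dm.D

    def predict(self, test: EpochSet) -> np.ndarray:
        _, labels = self._decode(test)
        return labels


@dataclass
class CnnClassPipeline:
    """Direct 6-class CNN classification."""

    n_classes: int = 6
    train_cfg: nets.TrainConfig = field(
        default_factory=lambda: nets.TrainConfig(epochs=40, batch=64)
    )
    higher_is_better = True

    def fit(self, train: EpochSet) -> "CnnClassPipeline":
        trunk = nets.build_trunk(
            n_channels=train.n_channels, n_times=train.n_times,
            seed=self.train_cfg.seed,
        )
        net = nets.build_class_head(trunk, self.n_classes,
                                    seed=self.train_cfg.seed + 1)
        self.net_, self.history_ = nets.train_classifier(
            net, train, cfg=self.train_cfg
        )
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        _, probs = nets.predict_classes(self.net_, test)
        return probs

    def predict(self, test: EpochSet) -> np.ndarray:
        labels, _ = nets.predict_classes(self.net_, test)
        return labels


@dataclass
class SiameseSinglePipeline:
    """Single multi-class Siamese model scored against support references."""

    n_classes: int = 6
    n_ref: int = 10
    train_cfg: nets.TrainConfig = field(
        default_factory=lambda: nets.TrainConfig(epochs=30, batch=256)
    )
    higher_is_better = True

    def fit(self, train: EpochSet) -> "SiameseSinglePipeline":
        trunk = nets.build_trunk(
            n_channels=train.n_channels, n_times=train.n_times,
            seed=self.train_cfg.seed,
        )
        net = nets.build_siamese(trunk, seed=self.train_cfg.seed + 1)
        self.net_ = nets.train_siamese(net, train, self.train_cfg)
        self.support_ = train
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        _, s = nets.siamese_score_multiclass(
            self.net_, test, self.support_, n_ref=self.n_ref,
            seed=self.train_cfg.seed, n_classes=self.n_classes,
        )
        return s

    def predict(self, test: EpochSet) -> np.ndarray:
        labels, _ = nets.siamese_score_multiclass(
            self.net_, test, self.support_, n_ref=self.n_ref,
            seed=self.train_cfg.seed, n_classes=self.n_classes,
        )
        return labels


@dataclass
class SiameseEnsemblePipeline:
    """Six per-class binary Siamese models, argmax over class similarities."""

    n_classes: int = 6
    n_ref: int = 10
    train_cfg: nets.TrainConfig = field(
        default_factory=lambda: nets.TrainConfig(epochs=30, batch=256)
    )
    higher_is_better = True

    def fit(self, train: EpochSet) -> "SiameseEnsemblePipeline":
        def factory() -> nets.Sequential:
            return nets.build_trunk(
                n_channels=train.n_channels, n_times=train.n_times,
                seed=self.train_cfg.seed,
            )

        self.models_ = nets.train_siamese_ensemble(
            factory, train, self.train_cfg, n_classes=self.n_classes
        )
        self.support_ = train
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        _, s, _ = nets.siamese_score_ensemble(
            self.models_, test, self.support_,
            n_ref=self.n_ref, seed=self.train_cfg.seed,
        )
        return s

    def predict(self, test: EpochSet) -> np.ndarray:
        labels, _, _ = nets.siamese_score_ensemble(
            self.models_, test, self.support_,
            n_ref=self.n_ref, seed=self.train_cfg.seed,
        )
        return labels


class AugmentedPipeline:
    """Wrap a pipeline with TA / TC temporal-shift handling."""

    def __init__(self, base: object, cfg: AugmentConfig) -> None:
        self.base = base
        self.cfg = cfg
        self.higher_is_better = base.higher_is_better

    def fit(self, train: EpochSet) -> "AugmentedPipeline":
        if self.cfg.mode in ("TA", "TA_TC") and self.cfg.alpha_shift > 0:
            train = expand_train(train, self.cfg)
        self.base.fit(train)
        return self

    def scores(self, test: EpochSet) -> np.ndarray:
        s, _ = combine_test(self.base.scores, test, self.cfg,
                            higher_is_better=self.higher_is_better)
        return s

    def predict(self, test: EpochSet) -> np.ndarray:
        _, labels = combine_test(self.base.scores, test, self.cfg,
                                 higher_is_better=self.higher_is_better)
        return labels


METHODS: dict[str, Callable[..., object]] = {
    "template_corr": TemplateCorrPipeline,
    "corr_blda": lambda **kw: BLDAPipeline(kind="corr", **kw),
    "cca_blda": lambda **kw: BLDAPipeline(kind="cca", **kw),
    "cnn_kbit_euclid": lambda **kw: CnnKbitPipeline(metric="euclid", **kw),
    "cnn_kbit_mahal": lambda **kw: CnnKbitPipeline(metric="mahal", **kw),
    "cnn_kbit_emd": lambda **kw: CnnKbitPipeline(metric="emd", **kw),
    "cnn_kbit_cemd": lambda **kw: CnnKbitPipeline(metric="cemd", **kw),
    "cnn_class": CnnClassPipeline,
    "siamese_single": SiameseSinglePipeline,
    "siamese_ensemble": SiameseEnsemblePipeline,
}


def make_pipeline(name: str, **kwargs) -> object:
    """Instantiate a method pipeline from the closed method vocabulary."""
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    return METHODS[name](**kwargs)
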