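"""Temporal-shift augmentation and test-time decision combination.

Small latency differences between sessions are emulated by shifting whole
epochs along the time axis.  Shifts are circular: the stimulus is periodic
with the epoch, and class identity is itself a circular code shift, so
wrap-around is the consistent choice (a truncate-and-zero-pad mode exists
behind a flag).

Four regimes, for a shift magnitude ``alpha`` in samples:

* NA     — no augmentation (baseline).
* TA     — training set expanded with copies shifted by -alpha and +alpha
           (3x the trials for alpha > 0); test untouched.
* TC     — scores from test inputs shifted by {-alpha, 0, +alpha} are
           averaged; probabilistic scorers are combined with argmax,
           distance scorers with argmin (the caller states which).
* TA&TC  — both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .synth import EpochSet

__all__ = ["AugmentConfig", "shift_epochs", "expand_train", "combine_test"]

_MODES = ("NA", "TA", "TC", "TA_TC")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation regime and shift magnitude in samples."""

    alpha_shift: int = 0
    mode: str = "NA"

    def __post_init__(self) -> None:
        if self.alpha_shift < 0:
            raise ValueError("alpha_shift must be >= 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    @property
    def train_shifts(self) -> tuple[int, ...]:
        if self.mode in ("TA", "TA_TC") and self.alpha_shift > 0:
            return (-self.alpha_shift, self.alpha_shift)
        return ()

    @property
    def test_shifts(self) -> tuple[int, ...]:
        if self.mode in ("TC", "TA_TC") and self.alpha_shift > 0:
            return (-self.alpha_shift, 0, self.alpha_shift)
        return (0,)


def shift_epochs(epochs: EpochSet, s: int, circular: bool = True) -> EpochSet:
    """Shift every trial by ``s`` samples along time; labels preserved.

    Circular shifts wrap, so ``s`` acts modulo the epoch length (a
    full-period shift is the identity); the truncating mode zero-pads and
    requires ``|s| < n_times``.
    """
    if not circular and abs(s) >= epochs.n_times:
        raise ValueError(f"|s|={abs(s)} must be < n_times={epochs.n_times}")
    out = epochs.copy()
    if circular:
        s = s % epochs.n_times
        if s:
            out.data = np.roll(epochs.data, s, axis=-1)
    elif s != 0:
        out.data = np.zeros_like(epochs.data)
        if s > 0:
            out.data[..., s:] = epochs.data[..., :-s]
        else:
            out.data[..., :s] = epochs.data[..., -s:]
    return out


def expand_train(train: EpochSet, cfg: AugmentConfig) -> EpochSet:
    """Original trials plus ±alpha shifted copies (TA / TA&TC only).

    Never mutates its input; session ids and labels are preserved on copies.
    """
    if cfg.mode not in ("TA", "TA_TC"):
        raise ValueError(f"expand_train requires mode TA or TA_TC, got {cfg.mode}")
    parts = [train.copy()]
    for s in cfg.train_shifts:
        parts.append(shift_epochs(train, s))
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        session_id=np.concatenate([p.session_id for p in parts]),
        subject_id=np.concatenate([p.subject_id for p in parts]),
        fs=train.fs,
        channel_names=train.channel_names,
    )


def combine_test(
    score_fn: Callable[[EpochSet], np.ndarray],
    test: EpochSet,
    cfg: AugmentConfig,
    higher_is_better: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Average score matrices over the shifted test views.

    ``score_fn`` maps an EpochSet to a (trials x classes) score matrix.
    Probability-like scores (``higher_is_better=True``) are combined with
    argmax; distance matrices with argmin.  Ties go to the lowest class
    index either way.  Returns (combined score matrix, labels).
    """
    scores = None
    for s in cfg.test_shifts:
        m = np.asarray(score_fn(shift_epochs(test, s)), dtype=np.float64)
        scores = m if scores is None else scores + m
    scores /= len(cfg.test_shifts)
    if higher_is_better:
        labels = np.argmax(scores, axis=1) + 1
    else:
        labels = np.argmin(scores, axis=1) + 1
    return scores, labels
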