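"""Synthetic multichannel c-VEP EEG generator.

No public recordings exist for this paradigm configuration, so the package
ships a simulator that reproduces the statistical structure every decoder
downstream assumes: a single-target 60 Hz on/off flicker driven by the
63-bit m-sequence, per-channel evoked impulse responses (class identity =
circular code shift), additive broadband + 1/f noise at a controlled SNR,
small trial-to-trial latency jitter, per-session multiplicative gain drift,
and a 5-session x 114-trial recording layout per subject.

The clean component of each trial is the zero-order-hold code waveform for
its class, circularly convolved (period ``Nt``) with the channel's evoked
kernel.  Circular convolution and circular jitter are the physically
faithful choices here: the stimulus is periodic with the epoch, and class
identity is itself a circular shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .codes import CodeBank, code_to_waveform

__all__ = [
    "KernelSpec",
    "SimConfig",
    "EpochSet",
    "DEFAULT_CHANNELS",
    "make_vep_kernel",
    "simulate_epochs",
    "write_epochs",
    "read_epochs",
]

DEFAULT_CHANNELS: tuple[str, ...] = ("O1", "O2", "Oz", "Pz", "P3", "P4", "PO7", "PO8")

# Occipital sites sit over primary visual cortex and carry the larger
# evoked response; parietal sites see an attenuated, slightly later copy.
_OCCIPITAL = {"O1", "O2", "Oz", "PO7", "PO8"}


@dataclass(frozen=True)
class KernelSpec:
    """Evoked impulse response of one channel: a Gaussian-windowed oscillation.

    latency_ms:  time of the response peak after a flash, in milliseconds.
    width_ms:    FWHM of the Gaussian envelope, in milliseconds.
    amplitude:   peak amplitude in microvolts.
    """

    latency_ms: float = 90.0
    width_ms: float = 60.0
    amplitude: float = 5.0
    carrier_hz: float = 10.0


def default_kernel_specs(
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
) -> tuple[KernelSpec, ...]:
    """Per-channel defaults: occipital amplitude 1.5x parietal."""
    return tuple(
        KernelSpec(amplitude=7.5 if name in _OCCIPITAL else 5.0)
        for name in channel_names
    )


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults mirror the paradigm the decoders target: 5 sessions of 114
    trials per subject, 8 occipito-parietal channels at 512 Hz, 60 Hz
    refresh, +10 dB evoked-to-noise ratio, ±2 samples of latency jitter and
    5% per-session gain spread with mixed white + 1/f background noise.
    """

    n_subjects: int = 1
    n_sessions: int = 5
    n_trials_per_session: int = 114
    fs: float = 512.0
    refresh_hz: float = 60.0
    n_channels: int = 8
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    kernel_specs: tuple[KernelSpec, ...] | None = None
    snr_db: float = 10.0
    jitter_samples: int = 2
    session_gain_sd: float = 0.05
    noise_model: str = "mixture"  # {white, pink, mixture}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.jitter_samples < 0:
            raise ValueError("jitter_samples must be >= 0")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.noise_model not in {"white", "pink", "mixture"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.kernel_specs is None:
            self.kernel_specs = default_kernel_specs(self.channel_names)
        if len(self.kernel_specs) != self.n_channels:
            raise ValueError("one KernelSpec per channel required")


@dataclass
class EpochSet:
    """Trials x channels x time EEG tensor with labels — the pipeline currency.

    labels are 1-based class indices (1..n_classes); session_id and
    subject_id are per-trial 1-based indices.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times) float64, microvolts
    labels: np.ndarray  # (n_trials,) int
    session_id: np.ndarray  # (n_trials,) int
    subject_id: np.ndarray  # (n_trials,) int
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.session_id = np.asarray(self.session_id, dtype=np.int64)
        self.subject_id = np.asarray(self.subject_id, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        n = self.data.shape[0]
        if not (self.labels.size == self.session_id.size == self.subject_id.size == n):
            raise ValueError("labels/session_id/subject_id must match trial count")
        if n and self.labels.min() < 1:
            raise ValueError("labels are 1-based")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_times(self) -> int:
        return int(self.data.shape[2])

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            labels=self.labels[mask],
            session_id=self.session_id[mask],
            subject_id=self.subject_id[mask],
            fs=self.fs,
            channel_names=self.channel_names,
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            labels=self.labels.copy(),
            session_id=self.session_id.copy(),
            subject_id=self.subject_id.copy(),
            fs=self.fs,
            channel_names=self.channel_names,
        )


def make_vep_kernel(
    kernel_specs: Sequence[KernelSpec], fs: float, n_times: int | None = None
) -> np.ndarray:
    """Build the channels x L impulse-response matrix.

    Each row is an amplitude-scaled Gaussian-windowed cosine whose peak sits
    at ``round(latency_ms/1000 * fs)`` samples.  Deterministic given specs.
    """
    kernels = []
    for spec in kernel_specs:
        if spec.width_ms <= 0:
            raise ValueError("kernel width must be positive")
        t0 = spec.latency_ms / 1000.0 * fs
        sigma = spec.width_ms / 1000.0 * fs / 2.355  # FWHM -> sigma
        length = int(round(t0 + 4 * sigma)) + 1
        if n_times is not None:
            length = min(length, n_times)
        t = np.arange(length, dtype=np.float64)
        env = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        kernels.append(
            spec.amplitude * env * np.cos(2 * np.pi * spec.carrier_hz * (t - t0) / fs)
        )
    length = max(k.size for k in kernels)
    out = np.zeros((len(kernels), length))
    for i, k in enumerate(kernels):
        out[i, : k.size] = k
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC power
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _background_noise(
    rng: np.random.Generator, shape: tuple[int, ...], model: str
) -> np.ndarray:
    if model == "white":
        return rng.standard_normal(shape)
    if model == "pink":
        return _pink_noise(rng, shape)
    # mixture: equal-power white + pink
    w = rng.standard_normal(shape)
    p = _pink_noise(rng, shape)
    return (w + p) / np.sqrt(2.0)


def simulate_epochs(
    config: SimConfig,
    bank: CodeBank,
    return_components: bool = False,
) -> EpochSet | tuple[EpochSet, np.ndarray, np.ndarray]:
    """Simulate labeled c-VEP epochs under ``config``.

    Per trial the clean signal is the class code waveform circularly
    convolved with the channel kernel, circularly delayed by an integer
    jitter drawn uniformly from [-jitter, +jitter]; noise is added to reach
    ``snr_db`` (clean power / noise power, over the whole trial); one
    multiplicative gain per session scales the entire trial.  Labels are
    balanced across classes as evenly as trial counts allow.  Fully
    reproducible given ``config.seed``.

    With ``return_components`` also returns the clean and noise tensors
    (post-gain), for SNR verification.
    """
    if bank.n_classes == 0:
        raise ValueError("empty code bank")
    rng = np.random.default_rng(config.seed)
    n_t = code_to_waveform(bank.row(0), config.refresh_hz, config.fs).size
    kernels = make_vep_kernel(config.kernel_specs, config.fs, n_times=n_t)

    # class templates: circular convolution of waveform with each kernel
    templates = np.empty((bank.n_classes, config.n_channels, n_t))
    for c in range(bank.n_classes):
        wave = code_to_waveform(bank.row(c), config.refresh_hz, config.fs)
        wf = np.fft.rfft(wave, n=n_t)
        for ch in range(config.n_channels):
            kf = np.fft.rfft(kernels[ch], n=n_t)
            templates[c, ch] = np.fft.irfft(wf * kf, n=n_t)
    templates -= templates.mean(axis=-1, keepdims=True)

    n_total = config.n_subjects * config.n_sessions * config.n_trials_per_session
    data = np.empty((n_total, config.n_channels, n_t))
    clean_all = np.empty_like(data)
    noise_all = np.empty_like(data)
    labels = np.empty(n_total, dtype=np.int64)
    session_id = np.empty(n_total, dtype=np.int64)
    subject_id = np.empty(n_total, dtype=np.int64)

    snr_lin = 10.0 ** (config.snr_db / 10.0)
    i = 0
    for subj in range(1, config.n_subjects + 1):
        for sess in range(1, config.n_sessions + 1):
            gain = 1.0 + config.session_gain_sd * rng.standard_normal()
            # balanced labels, order shuffled within the session
            reps = int(np.ceil(config.n_trials_per_session / bank.n_classes))
            sess_labels = np.tile(
                np.arange(1, bank.n_classes + 1), reps
            )[: config.n_trials_per_session]
            rng.shuffle(sess_labels)
            for lab in sess_labels:
                clean = templates[lab - 1]
                if config.jitter_samples > 0:
                    jit = int(
                        rng.integers(-config.jitter_samples, config.jitter_samples + 1)
                    )
                    clean = np.roll(clean, jit, axis=-1)
                noise = _background_noise(
                    rng, (config.n_channels, n_t), config.noise_model
                )
                p_sig = np.mean(clean**2)
                p_noise = np.mean(noise**2)
                noise = noise * np.sqrt(p_sig / (snr_lin * p_noise))
                data[i] = gain * (clean + noise)
                clean_all[i] = gain * clean
                noise_all[i] = gain * noise
                labels[i] = lab
                session_id[i] = sess
                subject_id[i] = subj
                i += 1

    epochs = EpochSet(
        data=data,
        labels=labels,
        session_id=session_id,
        subject_id=subject_id,
        fs=config.fs,
        channel_names=tuple(config.channel_names),
    )
    if return_components:
        return epochs, clean_all, noise_all
    return epochs


_REQUIRED_FIELDS = ("data", "labels", "session_id", "subject_id")


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write the canonical epoch container: HDF5 arrays + JSON metadata block."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", shuffle=True)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("session_id", data=epochs.session_id)
        f.create_dataset("subject_id", data=epochs.subject_id)
        f.attrs["meta"] = json.dumps(
            {"fs": epochs.fs, "channel_names": list(epochs.channel_names)}
        )


def read_epochs(path: str | Path) -> EpochSet:
    """Read the canonical epoch container; errors name any missing field."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_FIELDS:
            if name not in f:
                raise ValueError(f"missing {name}")
        if "meta" not in f.attrs:
            raise ValueError("missing meta")
        meta = json.loads(f.attrs["meta"])
        for key in ("fs", "channel_names"):
            if key not in meta:
                raise ValueError(f"missing {key}")
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            session_id=f["session_id"][()],
            subject_id=f["subject_id"][()],
            fs=float(meta["fs"]),
            channel_names=tuple(meta["channel_names"]),
        )
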