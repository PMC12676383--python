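"""Binary m-sequence stimulation codes for the c-VEP paradigm.

A c-VEP BCI drives an on/off flicker with a pseudorandom maximal-length
binary sequence (m-sequence).  Because circular shifts of an m-sequence are
nearly orthogonal (±1-mapped circular autocorrelation is ``K`` at lag 0 and
``-1`` at every other lag), each stimulus class is identified with one
circular shift of a single base code.  This module generates m-sequences
from a linear-feedback shift register (LFSR), ships the 63-bit code used
throughout the package as a fixture, builds the per-class code bank, and
expands codes from the bit domain to the EEG sample domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinaryCode",
    "CodeBank",
    "DEFAULT_SHIFTS",
    "generate_msequence",
    "reference_code",
    "circular_shift",
    "build_code_bank",
    "code_to_waveform",
]

#: Class-defining circular shifts, in bits, for the 6-class paradigm.
DEFAULT_SHIFTS: tuple[int, ...] = (0, 8, 16, 24, 32, 40)

# 63-bit maximal-length sequence driving the single-target flicker;
# validated to length 63 with 32 ones at load.
_REFERENCE_CODE = (
    "101011001101110110100100111000101111001010001100001000001111110"
)


@dataclass(frozen=True)
class BinaryCode:
    """A binary stimulation code of length ``K``."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("code must be a non-empty 1-D bit vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("code bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    @property
    def K(self) -> int:
        return int(self.bits.size)

    def bipolar(self) -> np.ndarray:
        """±1 mapping (0 -> -1, 1 -> +1) used for correlation identities."""
        return self.bits.astype(np.float64) * 2.0 - 1.0

    def to_string(self) -> str:
        return "".join("01"[b] for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "BinaryCode":
        s = "".join(s.split())
        if set(s) - {"0", "1"}:
            raise ValueError("code string may contain only '0'/'1' and whitespace")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryCode):
            return NotImplemented
        return self.bits.shape == other.bits.shape and bool(
            (self.bits == other.bits).all()
        )

    def __len__(self) -> int:
        return self.K


@dataclass(frozen=True)
class CodeBank:
    """One code row per stimulus class: circular shifts of a base code.

    Row ``i`` equals the base code circularly shifted by ``shifts[i]`` bits;
    rows are pairwise distinct.
    """

    codes: np.ndarray  # (n_classes, K) int8
    shifts: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return int(self.codes.shape[0])

    @property
    def K(self) -> int:
        return int(self.codes.shape[1])

    def row(self, cls_index: int) -> BinaryCode:
        return BinaryCode(self.codes[cls_index])

    def bipolar(self) -> np.ndarray:
        return self.codes.astype(np.float64) * 2.0 - 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base": "".join("01"[b] for b in self.codes[0]),
            "shifts": list(self.shifts),
            "codes": ["".join("01"[b] for b in row) for row in self.codes],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeBank":
        payload = json.loads(Path(path).read_text())
        codes = np.array(
            [[int(c) for c in row] for row in payload["codes"]], dtype=np.int8
        )
        return cls(codes=codes, shifts=tuple(payload["shifts"]))


def generate_msequence(
    degree: int,
    taps: Iterable[int] = (6, 1),
    init_state: Sequence[int] | None = None,
) -> BinaryCode:
    """Run a Fibonacci LFSR for one full period of ``2**degree - 1`` bits.

    ``taps`` lists the polynomial exponents whose registers feed back
    (e.g. ``{6, 1}`` for x^6 + x + 1).  The taps must form a primitive
    polynomial: a shorter-than-maximal period raises an error.
    """
    if degree < 2:
        raise ValueError("degree must be >= 2")
    taps = sorted(set(int(t) for t in taps))
    if not taps or taps[-1] > degree or taps[0] < 1:
        raise ValueError(f"taps must lie in 1..{degree}")
    if init_state is None:
        init_state = [0] * (degree - 1) + [1]
    state = [int(b) for b in init_state]
    if len(state) != degree:
        raise ValueError("init_state length must equal degree")
    if not any(state):
        raise ValueError("degenerate LFSR state: all-zero init_state is a fixed point")

    period = 2**degree - 1
    out = np.empty(period, dtype=np.int8)
    start = tuple(state)
    for k in range(period):
        out[k] = state[-1]
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = [fb] + state[:-1]
        if tuple(state) == start and k < period - 1:
            raise ValueError(
                f"non-primitive taps {taps}: LFSR period {k + 1} < {period}"
            )
    return BinaryCode(out)


def reference_code() -> BinaryCode:
    """The fixed 63-bit m-sequence used as the reference stimulation code."""
    return BinaryCode.from_string(_REFERENCE_CODE)


def circular_shift(code: BinaryCode, s: int) -> BinaryCode:
    """Circularly shift a code by ``s`` bits: output[k] = input[(k - s) mod K]."""
    s = int(s) % code.K
    return BinaryCode(np.roll(code.bits, s))


def build_code_bank(
    code: BinaryCode | None = None,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> CodeBank:
    """Stack circular shifts of a base code into the per-class code bank."""
    if code is None:
        code = reference_code()
    shifts = tuple(int(s) for s in shifts)
    if len(set(s % code.K for s in shifts)) != len(shifts):
        raise ValueError(f"duplicate shifts modulo K={code.K}: {shifts}")
    rows = np.stack([circular_shift(code, s).bits for s in shifts])
    return CodeBank(codes=rows, shifts=shifts)


def code_to_waveform(
    code: BinaryCode, refresh_hz: float = 60.0, fs: float = 512.0
) -> np.ndarray:
    """Zero-order-hold expansion of a bit code to the EEG sample domain.

    Sample ``t`` (0-based) carries bit ``floor(t * refresh_hz / fs)``; the
    output length is ``round(K * fs / refresh_hz)`` samples.  With the
    63-bit code, a 60 Hz screen refresh and 512 Hz sampling this yields the
    538-sample epoch the rest of the pipeline assumes.
    """
    if refresh_hz <= 0 or fs <= 0:
        raise ValueError("refresh_hz and fs must be positive")
    n_t = int(round(code.K * fs / refresh_hz))
    idx = np.minimum((np.arange(n_t) * refresh_hz / fs).astype(int), code.K - 1)
    return code.bits[idx].astype(np.float64)
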