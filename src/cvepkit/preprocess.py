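"""Epoch preprocessing: detrending, zero-phase bandpass, surface Laplacian.

The surface Laplacian acts as a spatial high-pass: each electrode's signal
has a distance-weighted sum of its neighbours subtracted, sharpening local
cortical activity and suppressing volume-conducted far sources.  Electrodes
live on a spherical head model, so inter-electrode distances are great-circle
(orthodromic) distances computed with the Vincenty arctangent formula, which
is numerically stable at both small and antipodal separations:

    d_ij = r * atan2(sqrt(a1^2 + a2^2), a3)

with a1 = cos(phi_j) sin(dlam), a2 = cos(phi_i) sin(phi_j) -
sin(phi_i) cos(phi_j) cos(dlam), a3 = sin(phi_i) sin(phi_j) +
cos(phi_i) cos(phi_j) cos(dlam).  Weights are inverse distances, truncated
at a cutoff radius of 1 in normalized head-radius units:

    w_ij = 1 / d_ij   for 0 < d_ij <= radius, else 0
    S'_i = S_i - sum_{j != i} w_ij S_j

The literal inverse-distance form rescales signal amplitude (row sums can
exceed 1); a ``normalized`` option rescales each row to sum 1 over its
nonzero entries, giving the conventional local-average-reference Laplacian.
The literal form is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .synth import EpochSet

__all__ = [
    "SensorLayout",
    "LaplacianWeights",
    "default_layout",
    "great_circle_distance",
    "laplacian_weights",
    "apply_laplacian",
    "detrend",
    "bandpass",
]


@dataclass(frozen=True)
class SensorLayout:
    """Electrode positions on a spherical head: latitude/longitude in radians."""

    names: tuple[str, ...]
    lat: np.ndarray
    lon: np.ndarray
    r: float = 1.0

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=np.float64)
        lon = np.asarray(self.lon, dtype=np.float64)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names")
        if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
            raise ValueError("latitude must lie in [-pi/2, pi/2]")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorLayout":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload["channels"].keys())
        lat = np.array([payload["channels"][n]["lat"] for n in names])
        lon = np.array([payload["channels"][n]["lon"] for n in names])
        return cls(names=names, lat=lat, lon=lon, r=float(payload.get("r", 1.0)))


def default_layout() -> SensorLayout:
    """The 8-channel occipito-parietal layout shipped with the package."""
    ref = resources.files("cvepkit").joinpath("data/layout_8ch.json")
    with resources.as_file(ref) as path:
        return SensorLayout.from_json(path)


@dataclass(frozen=True)
class LaplacianWeights:
    """Nonnegative neighbour weights with zero diagonal; zero beyond the radius."""

    W: np.ndarray
    radius: float = 1.0
    normalized: bool = False


def great_circle_distance(
    p1: tuple[float, float], p2: tuple[float, float], r: float = 1.0
) -> float:
    """Great-circle distance between (lat, lon) points on a sphere of radius r."""
    phi1, lam1 = p1
    phi2, lam2 = p2
    dlam = lam2 - lam1
    a1 = np.cos(phi2) * np.sin(dlam)
    a2 = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    a3 = np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(r * np.arctan2(np.hypot(a1, a2), a3))


def laplacian_weights(
    layout: SensorLayout, radius: float = 1.0, normalized: bool = False
) -> LaplacianWeights:
    """Inverse-great-circle-distance weights, truncated at ``radius``."""
    n = len(layout.names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_distance(
                (layout.lat[i], layout.lon[i]),
                (layout.lat[j], layout.lon[j]),
                layout.r,
            )
            if d == 0.0:
                raise ValueError(
                    f"zero inter-sensor distance between "
                    f"{layout.names[i]} and {layout.names[j]}"
                )
            D[i, j] = D[j, i] = d
    W = np.zeros_like(D)
    mask = (D > 0) & (D <= radius)
    W[mask] = 1.0 / D[mask]
    if normalized:
        row_sums = W.sum(axis=1, keepdims=True)
        nonzero = row_sums[:, 0] > 0
        W[nonzero] /= row_sums[nonzero]
    return LaplacianWeights(W=W, radius=radius, normalized=normalized)


def apply_laplacian(epochs: EpochSet, weights: LaplacianWeights) -> EpochSet:
    """S'_i = S_i - sum_j W_ij S_j, per trial and time point."""
    W = weights.W
    if W.shape[0] != epochs.n_channels:
        raise ValueError(
            f"weight matrix is {W.shape[0]}x{W.shape[1]} but epochs have "
            f"{epochs.n_channels} channels"
        )
    out = epochs.copy()
    out.data = epochs.data - np.einsum("ij,njt->nit", W, epochs.data)
    return out


def detrend(epochs: EpochSet) -> EpochSet:
    """Remove the least-squares line from each channel of each trial."""
    if epochs.n_times < 2:
        raise ValueError("need at least 2 time points to detrend")
    out = epochs.copy()
    out.data = sps.detrend(epochs.data, axis=-1, type="linear")
    return out


def bandpass(
    epochs: EpochSet,
    f_low: float = 0.5,
    f_high: float = 42.66,
    order: int = 4,
) -> EpochSet:
    """Zero-phase Butterworth bandpass (forward-backward, SOS form)."""
    fs = epochs.fs
    if not (0 < f_low < f_high < fs / 2):
        raise ValueError(
            f"invalid band [{f_low}, {f_high}] Hz for fs={fs} Hz"
        )
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    out = epochs.copy()
    out.data = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    return out
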