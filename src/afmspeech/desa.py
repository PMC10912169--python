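"""Energy-operator demodulation of a mono-component (DESA-1 variant).

The Teager energy operator ``psi[x][n] = x[n]^2 - x[n-1]*x[n+1]`` applied to
the signal and to its backward difference yields per-sample estimates of the
amplitude envelope and the instantaneous frequency.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from afmspeech.signal_model import SampledSignal

__all__ = [
    "DemodulationTracks",
    "DemodulationError",
    "teager_energy",
    "desa_demodulate",
]

_EPS = 1e-12
_EDGE_TRIM = 3           # operator + difference + median-filter support
_MEDIAN_WINDOW = 5
_BAD_FRACTION_LIMIT = 0.20
_G_OVERSHOOT = 0.1       # |G| beyond 1 by more than this counts as a failure


class DemodulationError(RuntimeError):
    """Signal is not demodulable as a single mono-component."""


@dataclass(frozen=True)
class DemodulationTracks:
    """Amplitude-envelope and instantaneous-frequency tracks for one component.

    Both tracks are aligned to the input's sample indices; estimates are
    trustworthy only inside ``valid_range`` (first and last valid index,
    inclusive).
    """

    ae: np.ndarray
    if_track: np.ndarray
    valid_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ae.shape != self.if_track.shape:
            raise ValueError("ae and if_track must have the same shape")
        lo, hi = self.valid_range
        if not 0 <= lo <= hi < self.ae.size:
            raise ValueError(f"invalid valid_range {self.valid_range}")

    @property
    def valid_slice(self) -> slice:
        lo, hi = self.valid_range
        return slice(lo, hi + 1)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "ae", "if"])
            for i, (a, f) in enumerate(zip(self.ae, self.if_track)):
                w.writerow([i, repr(float(a)), repr(float(f))])


def teager_energy(signal: SampledSignal | np.ndarray) -> np.ndarray:
    """Per-sample Teager energy; endpoints are NaN (undefined)."""
    x = signal.samples if isinstance(signal, SampledSignal) else np.asarray(signal, float)
    if x.size < 3:
        raise ValueError(f"need >= 3 samples, got {x.size}")
    psi = np.full(x.size, np.nan)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def _interpolate_bad(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linearly interpolate across flagged samples (edge-extend at ends)."""
    if not bad.any():
        return values
    good = ~bad
    idx = np.arange(values.size)
    return np.interp(idx, idx[good], values[good])


def desa_demodulate(signal: SampledSignal) -> DemodulationTracks:
    """DESA-1 demodulation into amplitude-envelope and IF tracks.

    Raises :class:`DemodulationError` when more than 20% of samples have
    non-positive signal energy or grossly out-of-range frequency estimates,
    which indicates the input is not a mono-component (or is too noisy).
    Isolated bad samples are repaired by linear interpolation; both tracks
    are median-filtered to suppress impulsive operator artifacts.
    """
    x = signal.samples
    n = x.size
    if n < 7:
        raise ValueError(f"need >= 7 samples, got {n}")

    psi_x = np.zeros(n)
    psi_x[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]

    y = np.zeros(n)
    y[1:] = x[1:] - x[:-1]
    psi_y = np.zeros(n)
    psi_y[1:-1] = y[1:-1] ** 2 - y[:-2] * y[2:]

    # G[n] = 1 - (psi_y[n] + psi_y[n+1]) / (4 psi_x[n]), interior n
    interior = slice(2, n - 2)
    idx = np.arange(n)[interior]
    denom = psi_x[interior]
    bad = denom <= 0
    if bad.mean() > _BAD_FRACTION_LIMIT:
        raise DemodulationError(
            f"{bad.mean():.0%} of samples have non-positive energy: "
            "not a mono-component / too noisy"
        )
    safe_denom = np.where(bad, _EPS, denom)
    g = 1.0 - (psi_y[idx] + psi_y[idx + 1]) / (4.0 * safe_denom)

    overshoot = np.abs(g) > 1.0 + _G_OVERSHOOT
    if (bad | overshoot).mean() > _BAD_FRACTION_LIMIT:
        raise DemodulationError(
            "too many out-of-range frequency estimates: "
            "not a mono-component / too noisy"
        )
    g_clamped = np.clip(g, -1.0, 1.0)
    omega = np.arccos(g_clamped)
    amp = np.sqrt(np.maximum(denom, 0.0) / np.maximum(1.0 - g_clamped**2, _EPS))

    repair = bad | overshoot
    omega = _interpolate_bad(omega, repair)
    amp = _interpolate_bad(amp, repair)

    ae = np.empty(n)
    if_track = np.empty(n)
    ae[interior] = medfilt(amp, _MEDIAN_WINDOW)
    if_track[interior] = medfilt(omega, _MEDIAN_WINDOW)
    # edge-extend so the arrays stay aligned with the input indices
    ae[: 2] = ae[2]
    ae[n - 2:] = ae[n - 3]
    if_track[: 2] = if_track[2]
    if_track[n - 2:] = if_track[n - 3]

    return DemodulationTracks(
        ae=ae, if_track=if_track, valid_range=(_EDGE_TRIM, n - 1 - _EDGE_TRIM)
    )
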