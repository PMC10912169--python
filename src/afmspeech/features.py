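"""Two-tone parametric fits to demodulated tracks and the 28-feature schema.

Each separated mono-component contributes 14 features: from the amplitude
envelope the mean amplitude plus two (depth, frequency, phase) AM tones, and
from the instantaneous-frequency track the carrier plus two FM tones.  Tone
fitting is spectral-peak initialization (Hann window, 4x zero padding)
followed by joint trust-region nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from afmspeech.desa import desa_demodulate
from afmspeech.fourier_bessel import separate_components
from afmspeech.signal_model import (
    PARAM_SYMBOLS,
    SampledSignal,
    ToneParams,
    wrap_phase,
)

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "AMEstimate",
    "FMEstimate",
    "estimate_am_params",
    "estimate_fm_params",
    "extract_features",
]

#: Fixed 28-name schema: component 1 (lower band) first, then component 2.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"c{i}_{sym}" for i in (1, 2) for sym in PARAM_SYMBOLS
)

DEGENERATE_TONE = ToneParams(0.0, 0.0, 0.0)

_MIN_TRACK_LENGTH = 64
_PEAK_MIN_BIN_SEPARATION = 3
_ZERO_PAD_FACTOR = 4
_NOISE_FLOOR_MULTIPLE = 5.0
_LS_MAX_ITER = 200
_LS_XTOL = 1e-10
# fraction of each separated component discarded before demodulation; the
# band-wise reconstruction rings near both ends of the analysis window
_EDGE_TRIM_FRACTION = 1.0 / 16.0


class AMEstimate(NamedTuple):
    amplitude: float
    tones: tuple[ToneParams, ToneParams]
    flags: tuple[str, ...]


class FMEstimate(NamedTuple):
    carrier: float
    tones: tuple[ToneParams, ToneParams]
    flags: tuple[str, ...]


@dataclass(frozen=True)
class FeatureVector:
    """Exactly 28 named features (14 per component) for one phoneme."""

    values: np.ndarray
    flags: tuple[str, ...] = ()
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", arr)
        if arr.shape != (28,):
            raise ValueError(f"feature vector must have exactly 28 entries, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("all features must be finite")
        for name, v in zip(self.names, arr):
            sym = name.split("_", 1)[1]
            if sym.startswith("mu") and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            if sym.startswith("omega") and not 0.0 <= v <= np.pi:
                raise ValueError(f"{name} must be in [0, pi], got {v}")
            if sym.startswith("theta") and not -np.pi <= v < np.pi:
                raise ValueError(f"{name} must be in [-pi, pi), got {v}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, (float(v) for v in self.values)))


class _TonePeak(NamedTuple):
    amp: float
    omega: float
    theta: float


def _spectral_tone_peaks(
    resid: np.ndarray, n0: int, max_tones: int = 2
) -> list[_TonePeak]:
    """Initial (amplitude, omega, theta) guesses from the windowed spectrum.

    Peaks below the per-bin median magnitude times a safety multiple are
    treated as noise; peaks below one cycle per window are unresolvable.
    Returned sorted by descending amplitude, ties broken toward lower
    frequency.
    """
    m = resid.size
    w = hann(m)
    n_fft = _ZERO_PAD_FACTOR * m
    spec = np.fft.rfft(resid * w, n=n_fft)
    mag = np.abs(spec)
    omega_bin = 2.0 * np.pi / n_fft

    idx, _ = find_peaks(mag, distance=_PEAK_MIN_BIN_SEPARATION)
    if idx.size == 0:
        return []
    omega_min = 2.0 * np.pi / m
    idx = idx[(idx * omega_bin >= omega_min) & (idx * omega_bin <= np.pi * 0.999)]
    if idx.size == 0:
        return []

    floor = _NOISE_FLOOR_MULTIPLE * np.median(mag)
    idx = idx[mag[idx] > max(floor, 1e2 * np.finfo(float).eps * max(mag.max(), 1.0))]
    if idx.size == 0:
        return []

    order = sorted(idx, key=lambda k: (-mag[k], k))[:max_tones]
    peaks = []
    for k in order:
        omega = k * omega_bin
        amp = 2.0 * mag[k] / w.sum()
        # the symmetric window's linear phase cancels at the peak bin, so the
        # bin angle is the tone phase at local index 0; refer it back to the
        # absolute index n0
        theta = float(wrap_phase(np.angle(spec[k]) - omega * n0))
        peaks.append(_TonePeak(amp=float(amp), omega=float(omega), theta=theta))
    return peaks


def _refine_tones(
    values: np.ndarray,
    n_idx: np.ndarray,
    offset0: float,
    peaks: Sequence[_TonePeak],
    multiplicative: bool,
) -> tuple[float, list[_TonePeak], tuple[str, ...]]:
    """Joint least-squares refinement of offset and tone parameters.

    ``multiplicative=True`` fits ``offset * (1 + sum a_i cos(...))`` (the AM
    envelope model); otherwise ``offset + sum a_i cos(...)`` (the IF model).
    """
    k = len(peaks)
    if k == 0:
        return offset0, [], ()

    p0 = [offset0]
    lower = [1e-12 if multiplicative else -np.inf]
    upper = [np.inf]
    omega_min = 2.0 * np.pi / values.size / 4.0
    for pk in peaks:
        amp0 = pk.amp / offset0 if multiplicative else pk.amp
        p0 += [max(amp0, 1e-12), pk.omega, pk.theta]
        lower += [0.0, omega_min, -2.0 * np.pi]
        upper += [np.inf, np.pi * (1 - 1e-9), 2.0 * np.pi]

    def model(p: np.ndarray) -> np.ndarray:
        mod = np.zeros_like(values)
        for j in range(k):
            a, om, th = p[1 + 3 * j : 4 + 3 * j]
            mod = mod + a * np.cos(om * n_idx + th)
        return p[0] * (1.0 + mod) if multiplicative else p[0] + mod

    res = least_squares(
        lambda p: model(p) - values,
        p0,
        bounds=(lower, upper),
        method="trf",
        xtol=_LS_XTOL,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=_LS_MAX_ITER * (len(p0) + 1),
    )
    flags: tuple[str, ...] = ()
    if res.status <= 0:
        # keep the spectral initialization rather than a half-converged state
        return offset0, list(peaks), ("ls_not_converged",)

    offset = float(res.x[0])
    tones = []
    for j in range(k):
        a, om, th = res.x[1 + 3 * j : 4 + 3 * j]
        tones.append(_TonePeak(float(a), float(om), float(wrap_phase(th))))
    # a tone that collapsed to numerical dust during refinement is no tone
    amp_scale = max(abs(offset), max(t.amp for t in tones))
    kept = [t for t in tones if t.amp > 1e-6 * amp_scale]
    if len(kept) < len(tones):
        flags = flags + ("tone_pruned",)
    return offset, kept, flags


def _order_and_pad(tones: list[ToneParams]) -> tuple[ToneParams, ToneParams]:
    live = sorted((t for t in tones if not t.is_degenerate), key=lambda t: t.omega)
    live += [DEGENERATE_TONE] * (2 - len(live))
    return live[0], live[1]


def _as_indices(values: np.ndarray, n_indices: np.ndarray | None) -> np.ndarray:
    if n_indices is None:
        return np.arange(values.size, dtype=np.float64)
    n_idx = np.asarray(n_indices, dtype=np.float64)
    if n_idx.shape != values.shape:
        raise ValueError("n_indices must match the track shape")
    return n_idx


def estimate_am_params(
    ae: np.ndarray, n_indices: np.ndarray | None = None
) -> AMEstimate:
    """Fit ``A * (1 + mu1*cos(w1*n+th1) + mu2*cos(w2*n+th2))`` to an envelope.

    ``n_indices`` gives the absolute sample index of each track value so that
    phases refer to the original signal's time origin.  Unresolvable tones
    come back degenerate (all zeros) with a flag.
    """
    ae = np.asarray(ae, dtype=np.float64)
    if ae.size < _MIN_TRACK_LENGTH:
        raise ValueError(f"need >= {_MIN_TRACK_LENGTH} valid samples, got {ae.size}")
    if np.median(ae) <= 0:
        raise ValueError("amplitude envelope must have positive median")
    n_idx = _as_indices(ae, n_indices)

    a0 = float(ae.mean())
    if a0 <= 0:
        raise ValueError(f"mean envelope amplitude must be > 0, got {a0}")
    resid = ae / a0 - 1.0
    peaks = _spectral_tone_peaks(resid, n0=int(n_idx[0]))
    flags: tuple[str, ...] = () if len(peaks) == 2 else ("am_degenerate_tone",)

    amplitude, tones, ls_flags = _refine_tones(ae, n_idx, a0, peaks, multiplicative=True)
    tone_params = [ToneParams(t.amp, t.omega, t.theta) for t in tones]
    return AMEstimate(
        amplitude=amplitude,
        tones=_order_and_pad(tone_params),
        flags=flags + ls_flags if len(peaks) < 2 else ls_flags,
    )


def estimate_fm_params(
    if_track: np.ndarray, n_indices: np.ndarray | None = None
) -> FMEstimate:
    """Fit ``w_c + sum_i mu_i*w_i*cos(w_i*n+th_i)`` to an IF track.

    The fitted tone amplitude ``b_i`` is converted to a modulation index as
    ``mu_i = b_i / w_i`` (an FM tone of depth mu appears in the IF with
    amplitude mu times its own frequency).
    """
    track = np.asarray(if_track, dtype=np.float64)
    if track.size < _MIN_TRACK_LENGTH:
        raise ValueError(f"need >= {_MIN_TRACK_LENGTH} valid samples, got {track.size}")
    n_idx = _as_indices(track, n_indices)

    wc0 = float(track.mean())
    resid = track - wc0
    peaks = _spectral_tone_peaks(resid, n0=int(n_idx[0]))
    flags: tuple[str, ...] = () if len(peaks) == 2 else ("fm_degenerate_tone",)

    carrier, tones, ls_flags = _refine_tones(track, n_idx, wc0, peaks, multiplicative=False)
    if not 0.0 < carrier < np.pi:
        raise ValueError(f"carrier estimate {carrier} outside (0, pi)")
    tone_params = [ToneParams(t.amp / t.omega, t.omega, t.theta) for t in tones]
    return FMEstimate(
        carrier=carrier,
        tones=_order_and_pad(tone_params),
        flags=flags + ls_flags if len(peaks) < 2 else ls_flags,
    )


def _component_feature_block(component: SampledSignal) -> tuple[list[float], tuple[str, ...]]:
    n = len(component)
    trim = max(8, int(n * _EDGE_TRIM_FRACTION))
    core = SampledSignal(component.samples[trim : n - trim], component.sample_rate)
    tracks = desa_demodulate(core)
    sl = tracks.valid_slice
    n_idx = np.arange(sl.start, sl.stop, dtype=np.float64) + trim

    am = estimate_am_params(tracks.ae[sl], n_idx)
    fm = estimate_fm_params(tracks.if_track[sl], n_idx)

    # schema order: A, omega_c, then the AM tones, then the FM tones
    ordered = [am.amplitude, fm.carrier]
    for tone in am.tones:
        ordered += [tone.mu, tone.omega, tone.theta]
    for tone in fm.tones:
        ordered += [tone.mu, tone.omega, tone.theta]
    return ordered, am.flags + fm.flags


def extract_features(signal: SampledSignal, fb_order: int | None = None) -> FeatureVector:
    """Full pipeline for one phoneme: separate, demodulate, fit, assemble.

    Deterministic: identical input yields an identical vector.  Errors from
    separation or demodulation propagate with the component index attached.
    """
    components = separate_components(signal, n_components=2, order=fb_order)
    values: list[float] = []
    flags: list[str] = []
    for i, comp in enumerate(components, start=1):
        try:
            block, comp_flags = _component_feature_block(comp)
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"component {i}: {exc}") from exc
        values.extend(block)
        flags.extend(f"c{i}_{f}" for f in comp_flags)
    return FeatureVector(values=np.array(values), flags=tuple(flags))
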