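"""Parametric two-tone AM / two-tone FM signal model.

A phoneme is modeled as the sum of two mono-components.  Each component is a
carrier whose amplitude is modulated by two cosine tones and whose phase is
modulated by two sine tones:

    s_i[n] = A * (1 + mu_a1*cos(w_a1*n + th_a1) + mu_a2*cos(w_a2*n + th_a2))
               * cos(w_c*n + mu_f1*sin(w_f1*n + th_f1)
                           + mu_f2*sin(w_f2*n + th_f2))

All angular frequencies are in radians per sample; conversion to Hz is
``f = omega * sample_rate / (2 * pi)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterError",
    "ToneParams",
    "AFMComponentParams",
    "SampledSignal",
    "synthesize_component",
    "synthesize_phoneme",
    "CarrierSeparationWarning",
    "PARAM_SYMBOLS",
]

#: Canonical ordering of the 14 per-component parameter symbols.
PARAM_SYMBOLS = (
    "A",
    "omega_c",
    "mu_a1",
    "omega_a1",
    "theta_a1",
    "mu_a2",
    "omega_a2",
    "theta_a2",
    "mu_f1",
    "omega_f1",
    "theta_f1",
    "mu_f2",
    "omega_f2",
    "theta_f2",
)


class ParameterError(ValueError):
    """Raised when a model parameter violates an invariant."""


class CarrierSeparationWarning(UserWarning):
    """Carriers may be too close for clean band separation."""


def wrap_phase(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle to the interval [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class ToneParams:
    """One modulating tone: depth ``mu``, frequency ``omega``, phase ``theta``.

    ``omega`` is in radians/sample and must lie in (0, pi) for a live tone;
    the degenerate tone (0, 0, 0) encodes "no tone" and is allowed so that
    estimators can return fixed-length parameter sets.
    """

    mu: float
    omega: float
    theta: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ParameterError(f"tone mu must be >= 0, got {self.mu}")
        if self.is_degenerate:
            return
        if not 0.0 < self.omega < np.pi:
            raise ParameterError(
                f"tone omega must be in (0, pi) rad/sample, got {self.omega}"
            )
        if not -np.pi <= self.theta < np.pi:
            raise ParameterError(
                f"tone theta must be in [-pi, pi), got {self.theta}"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.mu == 0.0 and self.omega == 0.0 and self.theta == 0.0


@dataclass(frozen=True)
class AFMComponentParams:
    """The 14 parameters of one mono-component.

    Serves both as synthesis input and as the estimator's output: amplitude
    ``A``, carrier ``omega_c`` (radians/sample), two AM tones and two FM
    tones, each tone a (mu, omega, theta) triple.
    """

    amplitude: float
    carrier: float
    am_tones: tuple[ToneParams, ToneParams]
    fm_tones: tuple[ToneParams, ToneParams]

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be > 0, got {self.amplitude}")
        if not 0.0 < self.carrier < np.pi:
            raise ParameterError(
                f"carrier must be in (0, pi) rad/sample, got {self.carrier}"
            )
        for label, tones in (("am", self.am_tones), ("fm", self.fm_tones)):
            if len(tones) != 2:
                raise ParameterError(f"exactly two {label} tones required")
            t1, t2 = tones
            if not t2.is_degenerate and not t1.is_degenerate and not t1.omega < t2.omega:
                raise ParameterError(
                    f"{label} tones must be in ascending omega order "
                    f"({t1.omega} !< {t2.omega})"
                )
            if t1.is_degenerate and not t2.is_degenerate:
                raise ParameterError(
                    f"degenerate {label} tone must come second"
                )
        mu_sum = self.am_tones[0].mu + self.am_tones[1].mu
        if mu_sum >= 1.0:
            raise ParameterError(
                f"sum of AM depths must be < 1 for a positive envelope, got {mu_sum}"
            )

    def to_dict(self) -> dict[str, float]:
        """Flat mapping keyed by the canonical symbol names."""
        a1, a2 = self.am_tones
        f1, f2 = self.fm_tones
        return {
            "A": self.amplitude,
            "omega_c": self.carrier,
            "mu_a1": a1.mu, "omega_a1": a1.omega, "theta_a1": a1.theta,
            "mu_a2": a2.mu, "omega_a2": a2.omega, "theta_a2": a2.theta,
            "mu_f1": f1.mu, "omega_f1": f1.omega, "theta_f1": f1.theta,
            "mu_f2": f2.mu, "omega_f2": f2.omega, "theta_f2": f2.theta,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AFMComponentParams":
        return cls(
            amplitude=float(d["A"]),
            carrier=float(d["omega_c"]),
            am_tones=(
                ToneParams(float(d["mu_a1"]), float(d["omega_a1"]), float(d["theta_a1"])),
                ToneParams(float(d["mu_a2"]), float(d["omega_a2"]), float(d["theta_a2"])),
            ),
            fm_tones=(
                ToneParams(float(d["mu_f1"]), float(d["omega_f1"]), float(d["theta_f1"])),
                ToneParams(float(d["mu_f2"]), float(d["omega_f2"]), float(d["theta_f2"])),
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "AFMComponentParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued waveform."""

    samples: np.ndarray
    sample_rate: float = 16000.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if arr.size < 5:
            raise ParameterError(f"signal must have >= 5 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("all samples must be finite")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")

    def __len__(self) -> int:
        return int(self.samples.size)


def _am_factor(params: AFMComponentParams, n: np.ndarray) -> np.ndarray:
    out = np.ones_like(n, dtype=np.float64)
    for tone in params.am_tones:
        if not tone.is_degenerate or tone.mu != 0.0:
            out = out + tone.mu * np.cos(tone.omega * n + tone.theta)
    return out


def _fm_phase(params: AFMComponentParams, n: np.ndarray) -> np.ndarray:
    phase = params.carrier * n
    for tone in params.fm_tones:
        if not tone.is_degenerate or tone.mu != 0.0:
            phase = phase + tone.mu * np.sin(tone.omega * n + tone.theta)
    return phase


def synthesize_component(
    params: AFMComponentParams, n_samples: int, sample_rate: float = 16000.0
) -> SampledSignal:
    """Synthesize one mono-component for sample indices 0 .. n_samples - 1."""
    if n_samples < 5:
        raise ParameterError(f"n_samples must be >= 5, got {n_samples}")
    n = np.arange(n_samples, dtype=np.float64)
    samples = params.amplitude * _am_factor(params, n) * np.cos(_fm_phase(params, n))
    return SampledSignal(samples=samples, sample_rate=sample_rate)


def carrier_separation_ok(
    comp1: AFMComponentParams, comp2: AFMComponentParams
) -> bool:
    """Heuristic check that FM/AM sidebands of the two carriers do not overlap."""
    spread = 0.0
    for comp in (comp1, comp2):
        wf = max(t.omega for t in comp.fm_tones)
        wa = max(t.omega for t in comp.am_tones)
        spread = max(spread, wf + wa)
    return abs(comp2.carrier - comp1.carrier) >= 4.0 * spread


def synthesize_phoneme(
    comp1: AFMComponentParams,
    comp2: AFMComponentParams,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = 16000.0,
) -> SampledSignal:
    """Synthesize a two-component phoneme, optionally with Gaussian noise.

    ``comp1`` must carry the lower band.  ``noise_sd = 0`` gives the exact
    noiseless model sum; with noise the output is reproducible from ``seed``.
    """
    if not comp1.carrier < comp2.carrier:
        raise ParameterError(
            "component 1 must have the lower carrier "
            f"({comp1.carrier} !< {comp2.carrier})"
        )
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if not carrier_separation_ok(comp1, comp2):
        warnings.warn(
            "carriers may be too close for clean band separation",
            CarrierSeparationWarning,
            stacklevel=2,
        )
    s1 = synthesize_component(comp1, n_samples, sample_rate)
    s2 = synthesize_component(comp2, n_samples, sample_rate)
    samples = s1.samples + s2.samples
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, n_samples)
    return SampledSignal(samples=samples, sample_rate=sample_rate)
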