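"""WAV reading/writing helpers.

Accepts 16-bit PCM or float WAV, mono or multi-channel (downmixed by
averaging with a warning); everything is resampled to the pipeline rate of
16 kHz so the radians/sample <-> Hz mapping is fixed.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from afmspeech.signal_model import SampledSignal

__all__ = ["PIPELINE_RATE", "read_wav", "write_wav"]

PIPELINE_RATE = 16000

_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str, target_rate: int = PIPELINE_RATE) -> SampledSignal:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: downmixing {data.shape[1]} channels by averaging")
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALES:
        data = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate)).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
    return SampledSignal(samples=data, sample_rate=float(target_rate))


def write_wav(path: str, signal: SampledSignal) -> None:
    """Write 16-bit PCM, normalizing only if the signal would clip."""
    x = signal.samples
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, int(signal.sample_rate), (x * 32767.0).astype(np.int16))
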