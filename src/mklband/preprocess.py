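"""Continuous-signal conditioning: re-reference, notch, downsample.

The canonical order is common-average reference, then line-noise notch
filtering, then anti-aliased downsampling to the working rate (436 Hz by
default).  Sessions are conditioned independently.
"""
from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ContinuousRecording

logger = logging.getLogger(__name__)

#: Default working sampling rate after downsampling, Hz.
DEFAULT_TARGET_HZ = 436.0


def common_average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract, at every sample, the instantaneous mean across channels."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    ref = rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=rec.data - ref)


def notch_line_noise(rec: ContinuousRecording, line_hz: float = 60.0,
                     n_harmonics: int = 3, q: float = 30.0) -> ContinuousRecording:
    """Zero-phase IIR notch at the line frequency and its harmonics.

    Harmonics at or above Nyquist are skipped with a warning.  Quality
    factor ``q`` sets the -3 dB bandwidth to ``f0/q`` (2 Hz at 60 Hz with
    the default q=30).
    """
    nyq = rec.sfreq_hz / 2.0
    if line_hz >= nyq:
        raise ValueError(f"line frequency {line_hz} Hz is at/above Nyquist {nyq} Hz")
    out = rec.data.copy()
    for h in range(1, n_harmonics + 1):
        f0 = line_hz * h
        if f0 >= nyq:
            logger.warning("skipping notch harmonic %.0f Hz (>= Nyquist %.1f Hz)", f0, nyq)
            continue
        b, a = signal.iirnotch(f0, q, fs=rec.sfreq_hz)
        out = signal.filtfilt(b, a, out, axis=0)
    return rec.copy_with(data=out)


def resample_to(rec: ContinuousRecording, target_hz: float = DEFAULT_TARGET_HZ,
                ) -> ContinuousRecording:
    """Polyphase anti-aliased downsampling to ``target_hz``.

    The output length is ``round(n_in * target_hz / sfreq_hz)``; the
    rational rate ratio is approximated to within 1e-9 relative.
    """
    if target_hz > rec.sfreq_hz:
        raise ValueError("upsampling not supported: target rate above input rate")
    if target_hz == rec.sfreq_hz:
        return rec.copy_with()
    ratio = Fraction(target_hz / rec.sfreq_hz).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.data, up, down, axis=0, padtype="line")
    n_out = int(round(rec.n_samples * target_hz / rec.sfreq_hz))
    if out.shape[0] > n_out:
        out = out[:n_out]
    elif out.shape[0] < n_out:  # pad by edge value; off-by-one from polyphase
        pad = np.repeat(out[-1:], n_out - out.shape[0], axis=0)
        out = np.vstack([out, pad])
    return rec.copy_with(data=out, sfreq_hz=float(target_hz))


def preprocess(rec: ContinuousRecording, line_hz: float = 60.0, n_harmonics: int = 3,
               target_hz: float = DEFAULT_TARGET_HZ, q: float = 30.0,
               ) -> ContinuousRecording:
    """Full conditioning chain: reference -> notch -> resample."""
    rec = common_average_reference(rec)
    rec = notch_line_noise(rec, line_hz=line_hz, n_harmonics=n_harmonics, q=q)
    rec = resample_to(rec, target_hz=target_hz)
    return rec
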