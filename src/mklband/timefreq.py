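"""Morlet time-frequency power, log rescaling and band averaging.

Power is estimated with 7-cycle complex Morlet wavelets on a geometric
frequency grid (29 values from 1 to 110 Hz by default), rescaled
point-wise by its logarithm, then averaged within the six canonical bands
and cropped to the 0-1000 ms window — the epochs carry +/-200 ms margins
precisely so that wavelet edge effects fall outside the analysis window.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bands import BandDefinition, CANONICAL_BANDS

#: Default wavelet frequency grid: geometric, 1-110 Hz, 29 values.
DEFAULT_N_FREQS = 29
DEFAULT_F_LO = 1.0
DEFAULT_F_HI = 110.0
DEFAULT_N_CYCLES = 7.0

#: Analysis window retained after decomposition, ms.
CROP_MS = (0.0, 1000.0)


def default_freq_grid(n: int = DEFAULT_N_FREQS, lo: float = DEFAULT_F_LO,
                      hi: float = DEFAULT_F_HI) -> np.ndarray:
    """Log-spaced frequency grid including both endpoints."""
    return np.geomspace(lo, hi, n)


@dataclass
class BandFeatureTensor:
    """Log band power, ``(n_epochs, n_channels, n_bands, n_times)``.

    The time axis covers the 0-1000 ms analysis window at the working
    sampling rate; each (channel, band) slice is the feature vector a
    kernel is built from.
    """

    values: np.ndarray
    band_names: list[str]
    ch_names: list[str]
    sfreq_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (epochs, channels, bands, time)")
        if self.values.shape[1] != len(self.ch_names):
            raise ValueError("channel axis mismatch")
        if self.values.shape[2] != len(self.band_names):
            raise ValueError("band axis mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite band features")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[3]


def morlet_wavelet(freq_hz: float, sfreq_hz: float,
                   n_cycles: float = DEFAULT_N_CYCLES,
                   zero_mean: bool = True) -> np.ndarray:
    """Complex Morlet wavelet at one centre frequency.

    Gaussian-windowed complex exponential with ``sigma_t = n_cycles /
    (2 pi f)``, truncated at +/-5 sigma_t, unit-energy normalised up to a
    conventional sqrt(2) factor (the same convention MNE uses, so power
    values are directly comparable).  ``zero_mean`` subtracts the small DC
    leak of the windowed oscillation.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    t = np.arange(0.0, 5.0 * sigma_t, 1.0 / sfreq_hz)
    t = np.concatenate([-t[::-1], t[1:]])
    osc = np.exp(2j * np.pi * freq_hz * t)
    if zero_mean:
        osc = osc - np.exp(-0.5 * (2.0 * np.pi * freq_hz * sigma_t) ** 2)
    w = osc * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    return w / (np.sqrt(0.5) * np.linalg.norm(w))


def morlet_power(epochs: np.ndarray, sfreq_hz: float,
                 freqs: np.ndarray | None = None,
                 n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Morlet wavelet power of an epoch tensor.

    The wavelets may be longer than the epoch (a 7-cycle wavelet at 1 Hz
    spans several seconds): convolution is linear with 'same' alignment,
    so low frequencies yield the expected heavily-smoothed power
    estimate rather than an error.

    Parameters
    ----------
    epochs
        ``(n_epochs, n_channels, n_times)`` real tensor; should include
        margins around the analysis window (edge effects are not removed
        here).
    sfreq_hz
        Sampling rate of the epoch tensor.
    freqs
        Wavelet centre frequencies; defaults to the 29-value geometric
        grid from 1 to 110 Hz.
    n_cycles
        Cycles per wavelet (constant across frequencies).

    Returns
    -------
    power : ``(n_epochs, n_channels, n_freqs, n_times)``, >= 0.
    """
    from scipy.signal import fftconvolve

    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= sfreq_hz / 2.0):
        raise ValueError("requested wavelet frequency at/above Nyquist")
    epochs = np.asarray(epochs, dtype=np.float64)
    n_ep, n_ch, n_t = epochs.shape
    flat = epochs.reshape(n_ep * n_ch, n_t)
    power = np.empty((n_ep * n_ch, len(freqs), n_t))
    # chunk the signal axis to keep fftconvolve buffers cache-friendly
    chunk = max(1, 2 ** 20 // max(n_t, 1))
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, sfreq_hz, n_cycles)[None, :]
        for s0 in range(0, flat.shape[0], chunk):
            sl = slice(s0, s0 + chunk)
            conv = fftconvolve(flat[sl].astype(complex), w, mode="same", axes=1)
            power[sl, fi, :] = np.abs(conv) ** 2
    return power.reshape(n_ep, n_ch, len(freqs), n_t)


def log_rescale(power: np.ndarray) -> np.ndarray:
    """Point-wise logarithm with a tiny floor to keep zero power finite.

    The floor is ``1e-12 * max(power)`` (or 1e-300 for an all-zero input).
    """
    power = np.asarray(power)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    mx = power.max() if power.size else 0.0
    eps = 1e-12 * mx if mx > 0 else 1e-300
    return np.log(power + eps)


def band_bin_membership(freqs: np.ndarray,
                        bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                        ) -> dict[str, np.ndarray]:
    """Grid-bin indices per band: half-open [lo, hi), hi inclusive for the
    highest band so the 110 Hz endpoint is not orphaned."""
    top = max(b.hi_hz for b in bands)
    out = {}
    for b in bands:
        if b.hi_hz == top:
            mask = (freqs >= b.lo_hz - 1e-9) & (freqs <= b.hi_hz + 1e-9)
        else:
            mask = (freqs >= b.lo_hz - 1e-9) & (freqs < b.hi_hz - 1e-9)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"band {b.name} contains no grid frequency")
        out[b.name] = idx
    return out


def band_average(logpower: np.ndarray, freqs: np.ndarray, sfreq_hz: float,
                 epoch_window_ms: tuple[float, float],
                 bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                 ch_names: list[str] | None = None,
                 crop_ms: tuple[float, float] = CROP_MS) -> BandFeatureTensor:
    """Average log power within bands, then crop to the analysis window.

    ``epoch_window_ms`` is the window the epochs were cut with (e.g.
    (-200, 1200)); the output time axis covers ``crop_ms`` (0-1000 ms by
    default), i.e. ``round(1 s * sfreq)`` samples at the working rate.
    """
    members = band_bin_membership(freqs, bands)
    n_ep, n_ch = logpower.shape[0], logpower.shape[1]
    i0 = int(round((crop_ms[0] - epoch_window_ms[0]) / 1000.0 * sfreq_hz))
    n_keep = int(round((crop_ms[1] - crop_ms[0]) / 1000.0 * sfreq_hz))
    if i0 < 0 or i0 + n_keep > logpower.shape[3]:
        raise ValueError("crop window exceeds epoch extent")
    out = np.empty((n_ep, n_ch, len(bands), n_keep))
    for bi, b in enumerate(bands):
        out[:, :, bi, :] = logpower[:, :, members[b.name], i0:i0 + n_keep].mean(axis=2)
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    return BandFeatureTensor(out, [b.name for b in bands], list(ch_names), sfreq_hz)


def compute_band_features(epochs: np.ndarray, sfreq_hz: float,
                          epoch_window_ms: tuple[float, float],
                          freqs: np.ndarray | None = None,
                          n_cycles: float = DEFAULT_N_CYCLES,
                          bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                          ch_names: list[str] | None = None) -> BandFeatureTensor:
    """Convenience chain: morlet_power -> log_rescale -> band_average."""
    if freqs is None:
        freqs = default_freq_grid()
    power = morlet_power(epochs, sfreq_hz, freqs, n_cycles)
    return band_average(log_rescale(power), np.asarray(freqs), sfreq_hz,
                        epoch_window_ms, bands, ch_names)


def save_features(feat: BandFeatureTensor, path: str | Path) -> None:
    np.savez(Path(path), values=feat.values, band_names=np.array(feat.band_names),
             ch_names=np.array(feat.ch_names), sfreq=feat.sfreq_hz)


def load_features(path: str | Path) -> BandFeatureTensor:
    with np.load(Path(path)) as z:
        return BandFeatureTensor(z["values"], [str(b) for b in z["band_names"]],
                                 [str(c) for c in z["ch_names"]], float(z["sfreq"]))
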