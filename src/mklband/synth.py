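"""Synthetic multichannel recordings with band-limited class effects.

Emulates a self-paced true/false judgment experiment: stimuli of a "math"
condition and of non-math conditions alternate in randomised order, each
displayed until a response after a variable reaction time, separated by a
fixed inter-stimulus interval.  Each channel is a sum of six band-limited
Gaussian-noise components (one per canonical band); during a math stimulus
the amplitude of chosen (channel, band) components is multiplied by
``effect_gain``, giving an exactly controllable class effect with known
ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, get_band
from .containers import ContinuousRecording, EventTable

#: Non-math conditions cycled through by the generator; cued rests last a
#: fixed 5 s and contribute several windows each, so the non-math window
#: pool comfortably exceeds the math pool (as in the paradigm emulated).
_NONMATH_CYCLE = ("self-episodic", "self-semantic", "self-judgment", "rest")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording.

    ``informative_pairs`` lists (channel index, band name) components whose
    amplitude is multiplied by ``effect_gain`` while a math stimulus is on
    screen; ``effect_gain = 1`` is an exact null.  Reaction times are drawn
    uniformly from ``rt_range_s``; consecutive stimuli are separated by
    ``isi_s`` (0.2 s by default, matching a typical self-paced paradigm), so
    events never overlap.
    """

    n_channels: int = 8
    sfreq_hz: float = 1000.0
    duration_s: float | None = None
    informative_pairs: tuple[tuple[int, str], ...] = ()
    effect_gain: float = 1.0
    n_events_per_class: int = 50
    rt_range_s: tuple[float, float] = (1.2, 2.6)
    isi_s: float = 0.2
    noise_model: str = "one_over_f"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels <= 0 or self.sfreq_hz <= 0 or self.n_events_per_class <= 0:
            raise ValueError("n_channels, sfreq_hz, n_events_per_class must be positive")
        if self.effect_gain < 0:
            raise ValueError("effect_gain must be >= 0")
        lo, hi = self.rt_range_s
        if not (0 < lo <= hi):
            raise ValueError("rt_range_s must satisfy 0 < min <= max")
        if self.isi_s < 0:
            raise ValueError("isi_s must be non-negative")
        if self.noise_model not in ("white", "one_over_f"):
            raise ValueError("noise_model must be 'white' or 'one_over_f'")
        for ch, band in self.informative_pairs:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"informative pair channel {ch} out of range")
            get_band(band)  # raises on unknown band


@dataclass
class SynthGroundTruth:
    """What the generator actually injected: events and informative pairs."""

    informative_pairs: tuple[tuple[int, str], ...]
    event_table: EventTable
    effect_gain: float
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


def _layout_events(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sequential non-overlapping events in randomised class order."""
    n = cfg.n_events_per_class
    conditions = ["math"] * n + [_NONMATH_CYCLE[i % len(_NONMATH_CYCLE)]
                                 for i in range(n)]
    order = rng.permutation(2 * n)
    conditions = [conditions[i] for i in order]
    rts = rng.uniform(cfg.rt_range_s[0], cfg.rt_range_s[1], size=2 * n)
    rts[np.asarray(conditions) == "rest"] = 0.0  # rests have no response
    onsets = np.empty(2 * n)
    t = 2.0  # lead-in so the -200 ms epoch margin stays in range
    for i in range(2 * n):
        onsets[i] = t
        dur = 5.0 if conditions[i] == "rest" else rts[i]
        t += dur + cfg.isi_s
    return pd.DataFrame({"onset_s": onsets, "condition": conditions, "rt_s": rts})


def _band_noise(n: int, lo: float, hi: float, sfreq: float,
                rng: np.random.Generator, one_over_f: bool) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to [lo, hi] via spectral masking.

    Synthesis in the frequency domain gives exact band limits and, for the
    one_over_f model, an amplitude spectrum shaped as 1/f^0.5 inside the band.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    mask = (f >= lo) & (f <= hi)
    spec[~mask] = 0.0
    if one_over_f:
        shape = np.zeros_like(f)
        shape[mask] = 1.0 / np.sqrt(f[mask])
        spec *= shape
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def generate_recording(cfg: SynthConfig) -> tuple[ContinuousRecording, SynthGroundTruth]:
    """Generate a recording plus ground truth; bit-reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    ev = _layout_events(cfg, rng)
    last_dur = 5.0 if ev["condition"].iloc[-1] == "rest" else ev["rt_s"].iloc[-1]
    needed = float(ev["onset_s"].iloc[-1] + last_dur) + 3.0
    duration = cfg.duration_s if cfg.duration_s is not None else needed
    if duration < needed:
        raise ValueError(
            f"duration_s={duration:.1f}s too short for "
            f"{2 * cfg.n_events_per_class} events (need >= {needed:.1f}s)")
    n = int(round(duration * cfg.sfreq_hz))

    # per-sample gain envelope for informative pairs: effect_gain while a
    # math stimulus is on screen, 1 otherwise
    t = np.arange(n) / cfg.sfreq_hz
    math_on = np.zeros(n, dtype=bool)
    for _, row in ev[ev["condition"] == "math"].iterrows():
        i0 = int(round(row["onset_s"] * cfg.sfreq_hz))
        i1 = int(round((row["onset_s"] + row["rt_s"]) * cfg.sfreq_hz))
        math_on[i0:i1] = True
    envelope = np.where(math_on, cfg.effect_gain, 1.0)

    informative = {(ch, get_band(b).name) for ch, b in cfg.informative_pairs}
    one_over_f = cfg.noise_model == "one_over_f"
    data = np.zeros((n, cfg.n_channels))
    for ch in range(cfg.n_channels):
        for band in CANONICAL_BANDS:
            comp = _band_noise(n, band.lo_hz, band.hi_hz, cfg.sfreq_hz, rng, one_over_f)
            if (ch, band.name) in informative:
                comp = comp * envelope
            data[:, ch] += comp

    rec = ContinuousRecording(data=data, sfreq_hz=cfg.sfreq_hz,
                              ch_names=[f"ch{i}" for i in range(cfg.n_channels)],
                              session_id=f"synth-seed{cfg.seed}")
    truth = SynthGroundTruth(
        informative_pairs=tuple((ch, get_band(b).name) for ch, b in cfg.informative_pairs),
        event_table=EventTable(ev), effect_gain=cfg.effect_gain)
    return rec, truth
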