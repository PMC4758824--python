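"""From a self-paced event table to labeled 1-second epochs.

Because reaction times vary widely, the continuous signal is cut into
contiguous 1 s windows aligned to integer seconds.  A window receives a
binary label (math / non-math) only if exactly one stimulus is on screen
during it: the event onset is rounded to the nearest integer second, its
duration (the reaction time; 5 s for cued rest) is floored, and every
candidate window is checked against the true, un-rounded intervals of all
events so that windows contaminated by a second stimulus are discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EventTable

logger = logging.getLogger(__name__)

LABEL_MATH = "math"
LABEL_NONMATH = "non-math"

#: Default epoch window around each 1 s window onset, ms.
DEFAULT_WINDOW_MS = (-200.0, 1200.0)


@dataclass
class LabeledEpochSet:
    """1 s windows with binary labels and provenance.

    ``epoch_starts_s`` are integer second marks; ``labels`` are
    ``"math"``/``"non-math"``; ``source_event`` indexes the event table row
    each window came from.
    """

    epoch_starts_s: np.ndarray
    labels: np.ndarray
    source_event: np.ndarray
    session_id: str = "session0"

    def __post_init__(self) -> None:
        self.epoch_starts_s = np.asarray(self.epoch_starts_s, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        self.source_event = np.asarray(self.source_event, dtype=int)
        if len({len(self.epoch_starts_s), len(self.labels), len(self.source_event)}) != 1:
            raise ValueError("field lengths differ")
        if len(np.unique(self.epoch_starts_s)) != len(self.epoch_starts_s):
            raise ValueError("epoch starts must be unique within a session")

    def __len__(self) -> int:
        return len(self.epoch_starts_s)

    @property
    def y(self) -> np.ndarray:
        """Labels as +/-1 (math = +1)."""
        return np.where(self.labels == LABEL_MATH, 1.0, -1.0)

    def subset(self, idx: np.ndarray) -> "LabeledEpochSet":
        return LabeledEpochSet(self.epoch_starts_s[idx], self.labels[idx],
                               self.source_event[idx], self.session_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_start_s": self.epoch_starts_s, "label": self.labels,
            "source_event": self.source_event, "session": self.session_id,
        })


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def label_windows(events: EventTable, rec_duration_s: float,
                  session_id: str = "session0") -> LabeledEpochSet:
    """Emit labeled 1 s windows from an event table.

    A candidate window of event *e* is kept only if *e* is the only
    stimulus present during it, judged on the true event intervals
    ``[onset, onset + duration)``.
    """
    onsets = events.onset_s
    durations = events.durations()  # true durations: RT, or 5 s for rest
    if len(onsets) and onsets[-1] + durations[-1] > rec_duration_s + 1e-9:
        logger.warning("events extend past recording end; trailing windows dropped")

    starts: list[int] = []
    labels: list[str] = []
    source: list[int] = []
    for k in range(len(events)):
        onset_r = _round_half_away(onsets[k])
        dur_r = int(np.floor(durations[k]))
        label = LABEL_MATH if events.condition[k] == "math" else LABEL_NONMATH
        for w in range(onset_r, onset_r + dur_r):
            if w < 0:
                continue
            if w + 1 > rec_duration_s:
                logger.warning("window [%d,%d) past recording end; dropped", w, w + 1)
                continue
            # single-stimulus rule on true intervals
            overlapping = np.flatnonzero((onsets < w + 1) & (onsets + durations > w))
            if len(overlapping) == 1 and overlapping[0] == k:
                starts.append(w)
                labels.append(label)
                source.append(k)
    order = np.argsort(starts, kind="stable")
    return LabeledEpochSet(np.asarray(starts)[order], np.asarray(labels, object)[order],
                           np.asarray(source)[order], session_id)


def balance_classes(epochs: LabeledEpochSet, seed: int) -> LabeledEpochSet:
    """Equalise class counts: keep all math windows, subsample non-math.

    The non-math pool (all non-math conditions pooled) is randomly
    subsampled without replacement; original temporal ordering is kept.
    """
    is_math = epochs.labels == LABEL_MATH
    n_math = int(is_math.sum())
    n_non = int((~is_math).sum())
    if n_math == 0 or n_non == 0:
        raise ValueError("both classes must be non-empty")
    if n_non < n_math:
        raise ValueError(f"cannot balance: {n_non} non-math < {n_math} math windows")
    if n_non == n_math:
        return epochs.subset(np.arange(len(epochs)))
    rng = np.random.default_rng(seed)
    non_idx = np.flatnonzero(~is_math)
    keep_non = np.sort(rng.choice(non_idx, size=n_math, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(is_math), keep_non]))
    return epochs.subset(keep)


def extract_epochs(rec: ContinuousRecording, epochs: LabeledEpochSet,
                   window_ms: tuple[float, float] = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Cut the epoch tensor ``(n_epochs, n_channels, n_samples)``.

    No baseline correction and no artifact rejection are applied; sample
    count per epoch is ``round(window_length * sfreq)``.
    """
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if w1 <= w0:
        raise ValueError("window end must exceed start")
    n_samp = int(round((w1 - w0) * rec.sfreq_hz))
    out = np.empty((len(epochs), rec.n_channels, n_samp))
    for i, start in enumerate(epochs.epoch_starts_s):
        i0 = int(round((start + w0) * rec.sfreq_hz))
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            raise ValueError(f"epoch at {start}s with window {window_ms} out of bounds")
        out[i] = rec.data[i0:i0 + n_samp].T
    return out
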