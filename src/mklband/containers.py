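"""In-memory containers and file I/O for recordings and event tables.

A recording travels as a plain ``samples x channels`` array plus sampling
rate and channel names.  On disk it is an NPZ or HDF5 file with datasets
``data``, ``sfreq`` and ``ch_names``; EDF import is supported for real
data.  Event tables are CSV files with header ``onset_s,condition,rt_s``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Event conditions recognised in event tables.
CONDITIONS = ("math", "self-episodic", "self-semantic", "self-judgment", "rest")

#: Fixed duration of a cued-rest period, in seconds.
REST_DURATION_S = 5.0


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)``.
    sfreq_hz
        Sampling rate in Hz.
    ch_names
        One name per channel, unique.
    session_id
        Free-form identifier of the recording session.
    """

    data: np.ndarray
    sfreq_hz: float
    ch_names: list[str] = field(default_factory=list)
    session_id: str = "session0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length must match channel count")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("ch_names must be unique")
        if self.sfreq_hz <= 0:
            raise ValueError("sfreq_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq_hz

    def copy_with(self, **kwargs) -> "ContinuousRecording":
        return replace(self, **kwargs)


def save_recording(rec: ContinuousRecording, path: str | Path) -> None:
    """Write a recording to ``.npz`` or ``.h5``/``.hdf5`` (by extension)."""
    path = Path(path)
    names = np.array(rec.ch_names, dtype=object)
    if path.suffix == ".npz":
        np.savez(path, data=rec.data, sfreq=rec.sfreq_hz,
                 ch_names=np.array(rec.ch_names), session_id=rec.session_id)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("sfreq", data=rec.sfreq_hz)
            f.create_dataset("ch_names", data=[n.encode() for n in names])
            f.attrs["session_id"] = rec.session_id
    else:
        raise ValueError(f"unsupported container extension {path.suffix!r}")


def load_recording(path: str | Path) -> ContinuousRecording:
    """Read a recording from ``.npz``, ``.h5``/``.hdf5`` or ``.edf``."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return ContinuousRecording(
                data=z["data"], sfreq_hz=float(z["sfreq"]),
                ch_names=[str(n) for n in z["ch_names"]],
                session_id=str(z["session_id"]) if "session_id" in z else "session0",
            )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return ContinuousRecording(
                data=f["data"][()], sfreq_hz=float(f["sfreq"][()]),
                ch_names=[n.decode() for n in f["ch_names"][()]],
                session_id=str(f.attrs.get("session_id", "session0")),
            )
    if path.suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return ContinuousRecording(
            data=raw.get_data().T, sfreq_hz=float(raw.info["sfreq"]),
            ch_names=list(raw.ch_names), session_id=path.stem,
        )
    raise ValueError(f"unsupported recording format {path.suffix!r}")


@dataclass
class EventTable:
    """Self-paced stimulus events: onset (s), condition, reaction time (s)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"onset_s", "condition", "rt_s"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        onsets = self.frame["onset_s"].to_numpy(dtype=float)
        if len(onsets) and onsets[0] < 0:
            raise ValueError("event onsets must be non-negative")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("event onsets must be non-decreasing")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        if np.any(self.frame["rt_s"].to_numpy(dtype=float) < 0):
            raise ValueError("negative reaction time")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onset_s(self) -> np.ndarray:
        return self.frame["onset_s"].to_numpy(dtype=float)

    @property
    def condition(self) -> np.ndarray:
        return self.frame["condition"].to_numpy(dtype=object)

    @property
    def rt_s(self) -> np.ndarray:
        return self.frame["rt_s"].to_numpy(dtype=float)

    def durations(self) -> np.ndarray:
        """True stimulus durations: reaction time, or 5 s for cued rest."""
        dur = self.rt_s.copy()
        dur[self.condition == "rest"] = REST_DURATION_S
        return dur


def save_events(events: EventTable, path: str | Path) -> None:
    events.frame.to_csv(path, index=False, columns=["onset_s", "condition", "rt_s"])


def load_events(path: str | Path) -> EventTable:
    return EventTable(pd.read_csv(path))


def load_coords(path: str | Path) -> pd.DataFrame:
    """Electrode coordinate table with columns channel, x, y[, z]."""
    df = pd.read_csv(path)
    if not {"channel", "x", "y"}.issubset(df.columns):
        raise ValueError("coordinate table needs columns channel, x, y")
    return df
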