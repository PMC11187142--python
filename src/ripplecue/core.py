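"""Core data containers: continuous recordings, epoched data and event tables.

Conventions used throughout the package:

* signals are in microvolts, channels x samples, with an explicit sampling
  rate ``fs`` in Hz;
* epoched data are trials x channels x time with a time axis in seconds
  relative to the lock event (t = 0 is the sample nearest the event onset);
* per-trial metadata live in a pandas DataFrame with one row per trial;
* channel roles tag each channel as ``scalp``, ``cortical`` or ``mtl``
  (medial temporal lobe); ripple analyses only apply to ``mtl`` channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_ROLES = ("scalp", "cortical", "mtl")

#: columns of the on-disk event-table format (tab separated)
EVENT_COLUMNS = [
    "channel", "type", "onset_s", "offset_s", "peak_s",
    "duration_s", "peak_amp", "n_cycles",
]


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel labels.
    roles : list of str
        Per-channel role, each one of ``scalp``, ``cortical`` or ``mtl``.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    roles: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if len(self.roles) != self.data.shape[0]:
            raise ValueError("one role per channel required")
        for r in self.roles:
            if r not in VALID_ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channels_by_role(self, role: str) -> list[str]:
        return [n for n, r in zip(self.ch_names, self.roles) if r == role]

    def pick(self, names: list[str]) -> "Recording":
        idx = [self.ch_names.index(n) for n in names]
        return Recording(self.data[idx].copy(), self.fs,
                         [self.ch_names[i] for i in idx],
                         [self.roles[i] for i in idx])

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.ch_names),
                         list(self.roles))


@dataclass
class EpochSet:
    """Epoched data: trials x channels x time plus per-trial labels.

    ``labels`` holds one row per trial; the columns the pipeline uses are
    ``class_`` (left / right / control), ``condition`` (retrieval / tmr),
    ``remembered`` (bool) and ``session`` (pre / post), but arbitrary extra
    columns are preserved by every operation.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: list[str]
    roles: list[str]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x channels x time")
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError("time axis length must match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        if len(self.labels) and len(self.labels) != self.data.shape[0]:
            raise ValueError("label rows must match trial count")
        if len(self.labels):
            self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_index(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        return int(np.argmin(np.abs(self.times - t)))

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.times >= window[0]) & (self.times <= window[1])

    def channels_by_role(self, role: str) -> list[str]:
        return [n for n, r in zip(self.ch_names, self.roles) if r == role]

    def pick_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.ch_names.index(n) for n in names]
        return EpochSet(self.data[:, idx].copy(), self.times.copy(), self.fs,
                        [self.ch_names[i] for i in idx],
                        [self.roles[i] for i in idx], self.labels.copy())

    def select_trials(self, index) -> "EpochSet":
        index = np.asarray(index)
        lab = self.labels.iloc[index].reset_index(drop=True) \
            if len(self.labels) else self.labels
        return EpochSet(self.data[index].copy(), self.times.copy(), self.fs,
                        list(self.ch_names), list(self.roles), lab)

    def crop(self, window: tuple[float, float]) -> "EpochSet":
        m = self.time_mask(window)
        return EpochSet(self.data[:, :, m].copy(), self.times[m].copy(),
                        self.fs, list(self.ch_names), list(self.roles),
                        self.labels.copy())

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), times=self.times.copy(),
                       ch_names=list(self.ch_names), roles=list(self.roles),
                       labels=self.labels.copy())


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("str" if c in ("channel", "type")
                                             else float))
                         for c in EVENT_COLUMNS})


def make_event_table(rows: list[dict]) -> pd.DataFrame:
    """Build an event table (ripples / spindles) from per-event dicts."""
    if not rows:
        return empty_event_table()
    df = pd.DataFrame(rows)
    for c in EVENT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[EVENT_COLUMNS]
    bad = df["onset_s"] > df["offset_s"]
    if bad.any():
        raise ValueError("event onset after offset")
    return df.reset_index(drop=True)
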