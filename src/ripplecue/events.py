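"""Ripple and spindle detection, and spindle-contact selection.

Ripples (80-120 Hz, MTL channels) are detected on the smoothed RMS of the
band-filtered signal: a 20 ms RMS window followed by a 20 ms moving-average
smoothing; an event is a contiguous run exceeding mean + 2 SD of the
smoothed RMS (statistics over the caller-supplied scope), lasting 25-300 ms
and containing at least three cycles. The event is timestamped at the
maximal negative band-filtered amplitude (``peak_mode="neg"``; switch to
``"abs"`` for the absolute extremum).

The spindle detector (12-15 Hz) uses the same machinery with a 200 ms RMS
window, mean + 1.5 SD and 0.5-3 s durations. It is a conventional
RMS-threshold detector; its duration statistics are implementation-defined
and should not be compared against published values obtained with other
detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochSet, Recording, make_event_table
from .filters import bandpass, moving_average


@dataclass
class RippleDetectParams:
    band: tuple[float, float] = (80.0, 120.0)
    rms_window: float = 0.020
    smooth_window: float = 0.020
    threshold_sd: float = 2.0
    min_dur: float = 0.025
    max_dur: float = 0.300
    min_cycles: int = 3
    merge_gap: float = 0.020
    peak_mode: str = "neg"  # "neg" | "abs"

    def __post_init__(self) -> None:
        if self.min_dur >= self.max_dur:
            raise ValueError("min_dur must be below max_dur")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")


@dataclass
class SpindleDetectParams:
    band: tuple[float, float] = (12.0, 15.0)
    rms_window: float = 0.200
    smooth_window: float = 0.200
    threshold_sd: float = 1.5
    min_dur: float = 0.5
    max_dur: float = 3.0
    min_cycles: int = 0
    merge_gap: float = 0.100
    peak_mode: str = "abs"


def count_cycles(segment: np.ndarray, band: tuple[float, float] | None,
                 fs: float | None) -> int:
    """Cycles in a segment: sign changes of the band-filtered trace // 2.

    Pass ``band=None`` when the segment is already band-filtered.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        return 0
    if band is not None:
        if fs is None:
            raise ValueError("fs required to filter the segment")
        segment = bandpass(segment, band, fs)
    s = np.sign(segment)
    # carry the previous sign through exact zeros
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    s = s[s != 0]
    if s.size < 2:
        return 0
    changes = int(np.sum(s[1:] != s[:-1]))
    return changes // 2


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) indices of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def _detect_band_events(rec: Recording, channels, params,
                        scope_mask: np.ndarray | None,
                        event_type: str) -> pd.DataFrame:
    fs = rec.fs
    if channels is None:
        channels = rec.channels_by_role("mtl") if event_type == "ripple" \
            else rec.channels_by_role("cortical") or rec.ch_names
    if scope_mask is None:
        scope_mask = np.ones(rec.n_samples, dtype=bool)
    scope_mask = np.asarray(scope_mask, dtype=bool)
    if scope_mask.shape[0] != rec.n_samples:
        raise ValueError("scope_mask length must match the recording")
    if not scope_mask.any():
        raise ValueError("empty scope_mask")

    n_rms = max(int(round(params.rms_window * fs)), 1)
    n_smooth = max(int(round(params.smooth_window * fs)), 1)
    gap = int(round(params.merge_gap * fs))

    rows = []
    for name in channels:
        x = rec.get_channel(name)
        filt = bandpass(x, params.band, fs)
        rms = np.sqrt(moving_average(filt ** 2, n_rms))
        smooth = moving_average(rms, n_smooth)
        mu = smooth[scope_mask].mean()
        sd = smooth[scope_mask].std()
        thr = mu + params.threshold_sd * sd
        runs = _merge_runs(_runs(smooth > thr), gap)
        for a, b in runs:
            dur = (b - a) / fs
            if dur < params.min_dur or dur > params.max_dur:
                continue
            seg = filt[a:b]
            n_cyc = count_cycles(seg, None, fs)
            if n_cyc < params.min_cycles:
                continue
            if params.peak_mode == "neg":
                pk = a + int(np.argmin(seg))
            else:
                pk = a + int(np.argmax(np.abs(seg)))
            rows.append(dict(channel=name, type=event_type,
                             onset_s=a / fs, offset_s=(b - 1) / fs,
                             peak_s=pk / fs, duration_s=dur,
                             peak_amp=filt[pk], n_cycles=float(n_cyc)))
    return make_event_table(rows)


def detect_ripples(rec: Recording, channels=None,
                   params: RippleDetectParams | None = None,
                   scope_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Detect ripple events; defaults to all MTL channels."""
    if rec.fs < 250:
        raise ValueError("ripple band not resolvable below fs = 250 Hz")
    return _detect_band_events(rec, channels,
                               params or RippleDetectParams(),
                               scope_mask, "ripple")


def detect_spindles(rec: Recording, channels=None,
                    params: SpindleDetectParams | None = None,
                    scope_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Detect spindle events; defaults to cortical channels."""
    if rec.fs < 50:
        raise ValueError("spindle band not resolvable below fs = 50 Hz")
    return _detect_band_events(rec, channels,
                               params or SpindleDetectParams(),
                               scope_mask, "spindle")


def _epochs_as_recording(ep: EpochSet) -> Recording:
    """Concatenate trials along time into a pseudo-continuous recording."""
    n_tr, n_ch, n_t = ep.data.shape
    data = np.transpose(ep.data, (1, 0, 2)).reshape(n_ch, n_tr * n_t)
    return Recording(data, ep.fs, list(ep.ch_names), list(ep.roles))


def detect_events_epochs(ep: EpochSet, detector, channels=None,
                         params=None) -> pd.DataFrame:
    """Run a detector over epoched data.

    Trials are concatenated so threshold statistics are computed across all
    data points of the epoch set; events straddling a trial boundary are
    discarded. Returned ``onset_s``/``peak_s``/``offset_s`` are relative to
    the epoch lock (t = 0), with an extra ``trial`` column.
    """
    rec = _epochs_as_recording(ep)
    ev = detector(rec, channels=channels, params=params)
    if not len(ev):
        ev = ev.copy()
        ev["trial"] = pd.Series(dtype=int)
        return ev
    n_t = ep.n_times
    trial_on = (ev["onset_s"] * ep.fs).round().astype(int) // n_t
    trial_off = (ev["offset_s"] * ep.fs).round().astype(int) // n_t
    ev = ev[trial_on == trial_off].copy()
    trial = ((ev["onset_s"] * ep.fs).round().astype(int) // n_t)
    t0 = ep.times[0]
    for col in ("onset_s", "offset_s", "peak_s"):
        ev[col] = ev[col] - trial * (n_t / ep.fs) + t0
    ev["trial"] = trial.to_numpy()
    return ev.reset_index(drop=True)


def select_spindle_contact(ep: EpochSet, band: tuple[float, float] = (12., 15.),
                           window: tuple[float, float] = (0.0, 1.5)) -> str:
    """Cortical channel with the strongest spindle-band power in ``window``.

    Power is the trial-averaged mean square of the band-filtered signal;
    ties break deterministically toward the first channel in order.
    """
    cort = ep.channels_by_role("cortical")
    if not cort:
        raise ValueError("no cortical channels")
    idx = [ep.ch_names.index(c) for c in cort]
    filt = bandpass(ep.data[:, idx], band, ep.fs, axis=-1)
    m = ep.time_mask(window)
    power = np.mean(filt[:, :, m] ** 2, axis=(0, 2))
    return cort[int(np.argmax(power))]
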