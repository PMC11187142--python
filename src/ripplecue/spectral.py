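"""Time-frequency decomposition, trial power scoring and event-locked PSD.

The TFR uses Hanning-tapered sliding-window Fourier estimates with a window
of five cycles per frequency, moving in 50 ms steps over a 1-25 Hz grid.
Time points where the window would exceed the epoch are set to NaN and
excluded (never zero-filled) from any averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .core import EpochSet, Recording


@dataclass
class TFR:
    """Power, trials x channels x freqs x times (NaN where undefined)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    zscored: bool = False

    def copy(self) -> "TFR":
        return TFR(self.power.copy(), self.freqs.copy(), self.times.copy(),
                   self.zscored)


def tfr_hanning(ep: EpochSet, freqs=None, step: float = 0.050,
                n_cycles: float = 5.0) -> TFR:
    """Sliding-window Hanning-tapered power per trial/channel/freq/time."""
    if freqs is None:
        freqs = np.arange(1.0, 26.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= ep.fs / 2):
        raise ValueError("frequencies at or above Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    t0, t1 = ep.times[0], ep.times[-1]
    out_times = np.arange(np.ceil(t0 / step) * step, t1 + 1e-9, step)
    n_tr, n_ch = ep.n_trials, ep.n_channels
    power = np.full((n_tr, n_ch, len(freqs), len(out_times)), np.nan)
    for fi, f in enumerate(freqs):
        n_win = int(round(n_cycles / f * ep.fs))
        if n_win < 3 or n_win > ep.n_times:
            continue  # window does not fit anywhere: stays NaN
        half = n_win // 2
        taper = np.hanning(n_win)
        osc = taper * np.exp(-2j * np.pi * f * np.arange(n_win) / ep.fs)
        for ti, t in enumerate(out_times):
            c = ep.time_index(t)
            lo, hi = c - half, c - half + n_win
            if lo < 0 or hi > ep.n_times:
                continue
            seg = ep.data[:, :, lo:hi]
            coef = seg @ osc
            power[:, :, fi, ti] = np.abs(coef) ** 2
    return TFR(power, freqs, out_times)


def zscore_tfr(tfr: TFR, window: tuple[float, float] | None = None) -> TFR:
    """Z-score power across time (per trial, channel and frequency)."""
    out = tfr.copy()
    if window is None:
        m = np.ones(len(tfr.times), dtype=bool)
    else:
        m = (tfr.times >= window[0]) & (tfr.times <= window[1])
        if not m.any():
            raise ValueError("z-scoring window outside TFR times")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(out.power[..., m], axis=-1, keepdims=True)
        sd = np.nanstd(out.power[..., m], axis=-1, ddof=1, keepdims=True)
    zero = (sd == 0) | ~np.isfinite(sd)
    if zero.any():
        warnings.warn("zero-variance TFR cells z-scored to 0")
        sd = np.where(zero, 1.0, sd)
        mu = np.where(np.isfinite(mu), mu, 0.0)
    out.power = (out.power - mu) / sd
    out.power[np.broadcast_to(zero, out.power.shape)] = 0.0
    out.zscored = True
    return out


def trial_power_score(tfr: TFR, mask: np.ndarray) -> np.ndarray:
    """Mean (z-)power over the masked (channels x) freqs x times cells,
    one scalar per trial; NaN cells are excluded."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cluster mask")
    if mask.ndim == 2:  # freqs x times: broadcast over channels
        sel = tfr.power[:, :, mask]
        axes = (1, 2)
    elif mask.ndim == 3:
        sel = tfr.power[:, mask]
        axes = (1,)
    else:
        raise ValueError("mask must be (channels x) freqs x times")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sel, axis=axes)


def rectangular_mask(tfr: TFR, freq_band: tuple[float, float] = (12.0, 16.0),
                     time_window: tuple[float, float] = (0.5, 1.5)
                     ) -> np.ndarray:
    """Fixed freqs x times fallback mask (spindle band, post-cue window)."""
    fm = (tfr.freqs >= freq_band[0]) & (tfr.freqs <= freq_band[1])
    tm = (tfr.times >= time_window[0]) & (tfr.times <= time_window[1])
    return np.outer(fm, tm)


def median_split(scores) -> tuple[np.ndarray, np.ndarray]:
    """Trial indices above the median (high) vs at/below it (low)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 trials to split")
    if np.all(scores == scores[0]):
        raise ValueError("all scores equal; median split undefined")
    med = np.median(scores)
    high = np.flatnonzero(scores > med)
    low = np.flatnonzero(scores <= med)
    return high, low


def psd_around_events(rec: Recording, events: pd.DataFrame,
                      half_window: float = 0.300) -> tuple[np.ndarray,
                                                           np.ndarray]:
    """Hanning-tapered periodogram of raw segments around event peaks,
    averaged over events. Returns (freqs, power)."""
    if not len(events):
        raise ValueError("no events")
    n_half = int(round(half_window * rec.fs))
    segs = []
    for _, ev in events.iterrows():
        c = int(round(ev["peak_s"] * rec.fs))
        lo, hi = c - n_half, c + n_half + 1
        if lo < 0 or hi > rec.n_samples:
            continue
        segs.append(rec.get_channel(ev["channel"])[lo:hi])
    if not segs:
        raise ValueError("no events fully inside the recording")
    segs = np.stack(segs)
    freqs, pxx = periodogram(segs, fs=rec.fs, window="hann", axis=-1)
    return freqs, pxx.mean(axis=0)
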