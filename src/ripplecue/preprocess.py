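"""Deterministic conditioning of continuous and epoched data.

The scalp pipeline downsamples to 200 Hz; the intracranial pipeline keeps
the native 1000 Hz. Epochs span [-1, 3] s around the lock event by default.
All operations preserve trial order and labels (documented drops excepted)
and are idempotent where the definition implies it (CAR, baseline,
z-scoring).
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .core import EpochSet, Recording
from .filters import moving_average

logger = logging.getLogger(__name__)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and resample to ``target_fs``.

    Pass-through (bit exact) when ``target_fs == fs``. Non-integer ratios
    are handled through a rational approximation of the rate ratio.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("target_fs may not exceed the current rate")
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(data, rec.fs * frac.numerator / frac.denominator,
                     list(rec.ch_names), list(rec.roles))


def epoch(rec: Recording, onsets, window: tuple[float, float],
          labels: pd.DataFrame | None = None) -> EpochSet:
    """Cut trials of ``window`` (s) around each onset.

    The sample at t = 0 is the recording sample nearest the onset. Onsets
    whose window falls outside the recording are skipped with a logged
    warning, and their label rows dropped.
    """
    onsets = np.asarray(onsets, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must be increasing")
    i0 = int(round(w0 * rec.fs))
    i1 = int(round(w1 * rec.fs))
    times = np.arange(i0, i1 + 1) / rec.fs
    n_times = len(times)

    trials, keep = [], []
    for k, on in enumerate(onsets):
        c = int(round(on * rec.fs))
        lo, hi = c + i0, c + i0 + n_times
        if lo < 0 or hi > rec.n_samples:
            logger.warning("onset %.3f s outside recording; trial dropped",
                           on)
            continue
        trials.append(rec.data[:, lo:hi])
        keep.append(k)
    n_drop = len(onsets) - len(keep)
    if n_drop:
        warnings.warn(f"dropped {n_drop} of {len(onsets)} onsets outside "
                      "the recording")
    data = (np.stack(trials) if trials
            else np.empty((0, rec.n_channels, n_times)))
    if labels is not None:
        labels = labels.iloc[keep].reset_index(drop=True)
    else:
        labels = pd.DataFrame(index=range(len(keep)))
    return EpochSet(data, times, rec.fs, list(rec.ch_names),
                    list(rec.roles), labels)


def common_average_reference(ep: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (CAR)."""
    if ep.n_channels < 2:
        raise ValueError("CAR undefined for a single channel")
    out = ep.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def zscore_across_trials(ep: EpochSet) -> EpochSet:
    """Z-score each (channel, time) cell across trials (sample SD, n-1).

    Zero-variance cells are set to 0 with a warning.
    """
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials to z-score across trials")
    out = ep.copy()
    mu = out.data.mean(axis=0, keepdims=True)
    sd = out.data.std(axis=0, ddof=1, keepdims=True)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance (channel, time) "
                      "cells set to 0")
        sd = np.where(zero, 1.0, sd)
    out.data = (out.data - mu) / sd
    out.data[np.broadcast_to(zero, out.data.shape)] = 0.0
    return out


def smooth_running_average(ep: EpochSet, width: float = 0.150) -> EpochSet:
    """Centered running average of ``width`` seconds along time.

    The window length in samples is rounded and forced odd (150 ms at
    200 Hz -> 31 samples); edges use shrinking windows so the output length
    equals the input length and constant input passes through unchanged.
    """
    n = int(round(width * ep.fs))
    if n % 2 == 0:
        n += 1
    if n < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    if n > ep.n_times:
        raise ValueError("smoothing window longer than the epoch")
    out = ep.copy()
    out.data = moving_average(out.data, n, axis=-1)
    return out


def baseline_whole_trial(ep: EpochSet) -> EpochSet:
    """Subtract, per trial and channel, the mean over the whole epoch."""
    out = ep.copy()
    out.data -= out.data.mean(axis=-1, keepdims=True)
    return out
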