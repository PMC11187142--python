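"""Cross-frequency coupling and peri-event timing measures.

Phase-amplitude coupling is quantified with the Modulation Index (MI): the
phase series is divided into 18 bins of 20 degrees, the mean amplitude per
bin is normalized to a distribution P, and MI is the Kullback-Leibler
distance of P from uniform, normalized by log(n_bins) so MI lies in [0, 1].

Phase convention throughout: Hilbert phase of the band-filtered signal,
0 at the filtered peak and +-pi at the trough, so ripples nesting toward
the spindle trough cluster around +-pi.

Comodulogram filter bandwidths follow the "fraction of the frequency of
interest" rule: full width 0.3 f for the phase-providing band and 0.7 f for
the amplitude-providing band, clamped to >= 1 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .filters import bandpass


@dataclass
class MIMatrix:
    mi: np.ndarray                     # low_freqs x high_freqs
    low_freqs: np.ndarray
    high_freqs: np.ndarray
    n_bins: int = 18
    surrogate_mi: np.ndarray | None = None  # reps x low x high

    def surrogate_percentile(self, q: float = 95.0) -> np.ndarray:
        if self.surrogate_mi is None:
            raise ValueError("no surrogates computed")
        return np.percentile(self.surrogate_mi, q, axis=0)


@dataclass
class PhaseStats:
    angles: np.ndarray
    mean_direction: float
    resultant_length: float
    v: float | None = None
    p: float | None = None
    extra: dict = field(default_factory=dict)


def instantaneous_phase(signal: np.ndarray,
                        band: tuple[float, float] = (12.0, 15.0),
                        fs: float = 1000.0, axis: int = -1) -> np.ndarray:
    """Hilbert phase (rad, (-pi, pi]) of the band-filtered signal."""
    if band[1] >= fs / 2:
        raise ValueError("band outside Nyquist")
    return np.angle(hilbert(bandpass(signal, band, fs, axis=axis),
                            axis=axis))


def _bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi) * n_bins)
    return np.clip(idx, 0, n_bins - 1).astype(np.intp)


def _mi_from_binned(sums: np.ndarray, counts: np.ndarray,
                    n_bins: int) -> float:
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    nz = p > 0
    kl = np.log(n_bins) + float(np.sum(p[nz] * np.log(p[nz])))
    return min(max(kl / np.log(n_bins), 0.0), 1.0)


def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     n_bins: int = 18) -> float:
    """MI in [0, 1] of the phase-conditional mean amplitude distribution.

    Empty phase bins contribute zero mass; all-zero amplitude returns 0
    with a warning; all mass in one bin gives MI = 1.
    """
    phase = np.asarray(phase).ravel()
    amp = np.asarray(amp).ravel()
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude must have equal length")
    if np.any(amp < 0):
        raise ValueError("amplitude must be non-negative")
    if not np.any(amp > 0):
        warnings.warn("all-zero amplitude; MI = 0 by convention")
        return 0.0
    idx = _bin_indices(phase, n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return _mi_from_binned(sums, counts, n_bins)


def _freq_band(f: float, frac: float) -> tuple[float, float]:
    half = max(frac * f, 1.0) / 2.0
    return (max(f - half, 0.1), f + half)


def _as_trials(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def comodulogram(phase_src: np.ndarray, amp_src: np.ndarray, fs: float,
                 low_freqs=None, high_freqs=None, bw_low: float = 0.3,
                 bw_high: float = 0.7, n_bins: int = 18) -> MIMatrix:
    """MI matrix over (phase frequency, amplitude frequency) pairs.

    ``phase_src`` / ``amp_src`` are (trials x time) event-locked segments
    (a 1-D array is treated as one trial); trials are concatenated before
    binning.
    """
    phase_src, amp_src = _as_trials(phase_src), _as_trials(amp_src)
    if low_freqs is None:
        low_freqs = np.arange(4.0, 21.0)
    if high_freqs is None:
        high_freqs = np.arange(20.0, 131.0, 5.0)
    low_freqs = np.asarray(low_freqs, dtype=float)
    high_freqs = np.asarray(high_freqs, dtype=float)

    phases = [np.angle(hilbert(bandpass(phase_src, _freq_band(f, bw_low),
                                        fs, axis=-1), axis=-1)).ravel()
              for f in low_freqs]
    amps = [np.abs(hilbert(bandpass(amp_src, _freq_band(f, bw_high),
                                    fs, axis=-1), axis=-1)).ravel()
            for f in high_freqs]

    mi = np.zeros((len(low_freqs), len(high_freqs)))
    for i, ph in enumerate(phases):
        idx = _bin_indices(ph, n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        for j, am in enumerate(amps):
            sums = np.bincount(idx, weights=am, minlength=n_bins)
            mi[i, j] = _mi_from_binned(sums, counts, n_bins)
    return MIMatrix(mi, low_freqs, high_freqs, n_bins)


def mi_surrogates(phase_src: np.ndarray, amp_src: np.ndarray, fs: float,
                  low_freqs=None, high_freqs=None, n: int = 100,
                  seed: int | None = None, bw_low: float = 0.3,
                  bw_high: float = 0.7, n_bins: int = 18) -> MIMatrix:
    """Observed MI matrix plus a trial-shuffled surrogate distribution.

    Surrogates permute the trial assignment of the amplitude-providing
    segments relative to the phase-providing ones (MI recomputed per
    permutation); requires >= 3 trials.
    """
    phase_src, amp_src = _as_trials(phase_src), _as_trials(amp_src)
    if phase_src.shape[0] < 3:
        raise ValueError("need >= 3 trials for trial-shuffled surrogates")
    if n < 1:
        raise ValueError("n must be >= 1")
    if low_freqs is None:
        low_freqs = np.arange(4.0, 21.0)
    if high_freqs is None:
        high_freqs = np.arange(20.0, 131.0, 5.0)
    low_freqs = np.asarray(low_freqs, dtype=float)
    high_freqs = np.asarray(high_freqs, dtype=float)
    rng = np.random.default_rng(seed)
    n_tr, n_t = phase_src.shape

    bin_idx = np.stack([
        _bin_indices(np.angle(hilbert(bandpass(
            phase_src, _freq_band(f, bw_low), fs, axis=-1), axis=-1)),
            n_bins)
        for f in low_freqs])                       # n_low x trials x time
    amp_env = np.stack([
        np.abs(hilbert(bandpass(amp_src, _freq_band(f, bw_high), fs,
                                axis=-1), axis=-1))
        for f in high_freqs])                      # n_high x trials x time

    def _matrix(perm: np.ndarray) -> np.ndarray:
        out = np.zeros((len(low_freqs), len(high_freqs)))
        for i in range(len(low_freqs)):
            idx = bin_idx[i].ravel()
            counts = np.bincount(idx, minlength=n_bins)
            for j in range(len(high_freqs)):
                am = amp_env[j, perm].ravel()
                sums = np.bincount(idx, weights=am, minlength=n_bins)
                out[i, j] = _mi_from_binned(sums, counts, n_bins)
        return out

    observed = _matrix(np.arange(n_tr))
    sur = np.stack([_matrix(rng.permutation(n_tr)) for _ in range(n)])
    return MIMatrix(observed, low_freqs, high_freqs, n_bins,
                    surrogate_mi=sur)


def phase_at_events(phase: np.ndarray, fs: float, event_times,
                    t0: float = 0.0,
                    window: tuple[float, float] | None = None) -> np.ndarray:
    """Nearest-sample phase at each event time (times in s, series starts
    at ``t0``); events outside ``window`` (if given) are dropped."""
    phase = np.asarray(phase)
    event_times = np.asarray(event_times, dtype=float)
    if window is not None:
        event_times = event_times[(event_times >= window[0]) &
                                  (event_times <= window[1])]
    if event_times.size == 0:
        return np.array([])
    idx = np.round((event_times - t0) * fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= phase.shape[-1]):
        raise ValueError("event time outside the phase series")
    return phase[..., idx]


def circular_mean(angles) -> tuple[float, float]:
    """Mean direction and resultant length R of a set of angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(1j * angles).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        warnings.warn("resultant length ~ 0; mean direction undefined")
        return 0.0, 0.0
    return float(np.angle(z)), r


def peri_event_histogram(event_times_per_trial, window: tuple[float, float],
                         bin_width: float = 0.050
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Event rate (events/s) in fixed bins, averaged over trials.

    rate(bin) = count(bin) / (n_trials * bin_width); the conservation
    identity sum(rate) * bin_width * n_trials = total in-window events
    holds exactly.
    """
    if len(event_times_per_trial) < 1:
        raise ValueError("need at least one trial")
    w0, w1 = window
    if bin_width > (w1 - w0):
        raise ValueError("bin wider than the window")
    edges = w0 + bin_width * np.arange(int(np.floor((w1 - w0) / bin_width))
                                       + 1)
    counts = np.zeros(len(edges) - 1)
    for evs in event_times_per_trial:
        evs = np.asarray(evs, dtype=float)
        if evs.size:
            counts += np.histogram(evs, bins=edges)[0]
    n_trials = len(event_times_per_trial)
    rate = counts / (n_trials * bin_width)
    centers = edges[:-1] + bin_width / 2
    return centers, rate


def event_onset_cross_histogram(ripple_onsets, spindle_onsets,
                                half_window: float = 1.0,
                                bin_width: float = 0.050
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Ripple-onset lags to the nearest spindle onset, as % of ripples."""
    ripple_onsets = np.asarray(ripple_onsets, dtype=float)
    spindle_onsets = np.asarray(spindle_onsets, dtype=float)
    if ripple_onsets.size == 0 or spindle_onsets.size == 0:
        raise ValueError("both event tables must be non-empty")
    lags = np.array([r - spindle_onsets[np.argmin(np.abs(spindle_onsets - r))]
                     for r in ripple_onsets])
    n_bins = int(round(2 * half_window / bin_width))
    edges = -half_window + bin_width * np.arange(n_bins + 1)
    counts = np.histogram(lags, bins=edges)[0]
    centers = edges[:-1] + bin_width / 2
    return centers, 100.0 * counts / ripple_onsets.size
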