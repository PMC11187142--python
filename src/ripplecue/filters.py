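"""Shared filtering primitives.

All band-pass filtering in this package is zero-phase (two-pass) Butterworth,
order 3 per pass, applied with second-order sections for numerical stability.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
             order: int = 3, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis``."""
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    n = x.shape[axis]
    # sosfiltfilt needs padlen < n; shrink for short segments
    padlen = min(3 * (2 * sos.shape[0] + 1) * 2, n - 1)
    return sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def envelope(x: np.ndarray, band: tuple[float, float], fs: float,
             axis: int = -1) -> np.ndarray:
    """Amplitude envelope (|Hilbert|) of the band-filtered signal."""
    return np.abs(hilbert(bandpass(x, band, fs, axis=axis), axis=axis))


def moving_average(x: np.ndarray, n: int, axis: int = -1) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if n < 1:
        raise ValueError("window must span at least one sample")
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    kernel = np.ones(n)
    num = np.apply_along_axis(np.convolve, -1, x, kernel, "same") \
        if x.ndim > 1 else np.convolve(x, kernel, "same")
    den = np.convolve(np.ones(x.shape[-1]), kernel, "same")
    return np.moveaxis(num / den, -1, axis)
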