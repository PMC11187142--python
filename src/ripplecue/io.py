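"""File I/O: EDF recordings and tab-separated event / label tables.

Reading EDF goes through :func:`mne.io.read_raw_edf`. Writing uses a small
EDF+ compatible writer (16-bit samples, one data record per second): the
synthetic recordings this package produces are plain continuous signals, so
the minimal subset of the format suffices, and the writer is verified by
round-tripping through MNE's reader in the test suite.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, Recording, empty_event_table

_ROLE_KEY = "roles"


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to an EDF file (16-bit, 1-s data records).

    The signal is scaled to the per-channel physical range and quantized to
    16 bits; the last partial second is zero-padded. Channel roles are not
    part of EDF and are stored alongside in ``<path>.roles.tsv``.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_max, dig_min = 32767, -32768

    buf = _io.BytesIO()
    header_bytes = 256 * (1 + n_ch)
    buf.write(_pad("0", 8))
    buf.write(_pad("X X X X", 80))
    buf.write(_pad("Startdate 01-JAN-2000 X X X", 80))
    buf.write(_pad("01.01.00", 8))
    buf.write(_pad("00.00.00", 8))
    buf.write(_pad(str(header_bytes), 8))
    buf.write(_pad("EDF+C", 44))
    buf.write(_pad(str(n_rec), 8))
    buf.write(_pad("1", 8))
    buf.write(_pad(str(n_ch), 4))
    for name in rec.ch_names:
        buf.write(_pad(name, 16))
    for _ in range(n_ch):
        buf.write(_pad("", 80))
    for _ in range(n_ch):
        buf.write(_pad("uV", 8))
    for p in phys_max:
        buf.write(_pad(f"{-p:.6g}"[:8], 8))
    for p in phys_max:
        buf.write(_pad(f"{p:.6g}"[:8], 8))
    for _ in range(n_ch):
        buf.write(_pad(str(dig_min), 8))
    for _ in range(n_ch):
        buf.write(_pad(str(dig_max), 8))
    for _ in range(n_ch):
        buf.write(_pad("", 80))
    for _ in range(n_ch):
        buf.write(_pad(str(fs), 8))
    for _ in range(n_ch):
        buf.write(_pad("", 32))

    # physical -> digital with the same affine map the reader inverts
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.empty((n_ch, n_rec * fs), dtype="<i2")
    for c in range(n_ch):
        d = np.round((padded[c] + phys_max[c]) * scale[c] + dig_min)
        digital[c] = np.clip(d, dig_min, dig_max).astype("<i2")
    for r in range(n_rec):
        sl = slice(r * fs, (r + 1) * fs)
        buf.write(digital[:, sl].tobytes())

    path.write_bytes(buf.getvalue())
    roles_path = path.with_suffix(path.suffix + ".roles.tsv")
    pd.DataFrame({"channel": rec.ch_names, "role": rec.roles}).to_csv(
        roles_path, sep="\t", index=False)
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts).

    Channel roles are restored from ``<path>.roles.tsv`` when present,
    otherwise every channel is tagged ``scalp``.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    names = list(raw.ch_names)
    roles_path = path.with_suffix(path.suffix + ".roles.tsv")
    if roles_path.exists():
        tbl = pd.read_csv(roles_path, sep="\t")
        role_of = dict(zip(tbl["channel"], tbl["role"]))
        roles = [role_of.get(n, "scalp") for n in names]
    else:
        roles = ["scalp"] * len(names)
    return Recording(data, float(raw.info["sfreq"]), names, roles)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table (ripples / spindles) as TSV."""
    path = Path(path)
    out = events.copy()
    for c in EVENT_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not len(df):
        return empty_event_table()
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any label / ground-truth table as TSV."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
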