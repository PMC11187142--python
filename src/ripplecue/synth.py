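"""Ground-truth simulator for NREM-like recordings.

The generator reproduces the statistical structure the analysis pipeline
assumes, with every injected event bookkept so each stage can be validated
against a known answer:

* 1/f^slope Gaussian background on every channel;
* cue-evoked slow-oscillation (SO, < 1 Hz) half-waves followed by
  spindle bursts (12-15 Hz, Gaussian-windowed, ~0.75 s) on cortical
  channels, nesting the spindle in the SO upstate;
* ripple bursts (80-120 Hz band, 25-150 ms) on MTL channels whose timing
  relative to the concurrent spindle phase is drawn von Mises(mu, kappa) --
  the generative analogue of ripples nesting toward the spindle trough
  (phase convention: 0 = spindle peak, +-pi = trough);
* cue trials at ~5.5 s intervals; class-specific multichannel patterns
  injected during retrieval and, for learning-cue trials, time-locked to
  the injected spindle/ripple window during TMR. Trials flagged as
  not-remembered carry no pattern.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimParams.seed``; identical parameters give bit-identical output. Draw
order per operation: background noise (channel by channel), event jitters,
coupling angles, class templates, remembered flags, label shuffling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import EpochSet, Recording

_KAPPA_CAP = 500.0  # effectively deterministic angles


@dataclass
class SimParams:
    """Parameters of the synthetic NREM study.

    Rates are per opportunity window (events per trial, or per spindle for
    ripples) so that event counts scale linearly and deterministically with
    the rate. ``pattern_snr`` scales the class template relative to the
    per-channel background standard deviation; ``spindle_snr`` and
    ``ripple_snr`` scale burst peak amplitude relative to the broadband
    background RMS (= ``background_sd``).
    """

    fs: float = 1000.0
    n_channels: int = 8
    channel_roles: tuple[str, ...] | None = None  # default: 3/4 cortical, rest mtl
    duration: float | None = None                 # s; derived from trials if None
    n_trials: int = 40        # per class (left/right) and for the control cue
    iti: float = 5.5          # inter-trial interval, s
    iti_jitter: float = 0.2   # s, uniform
    epoch_window: tuple[float, float] = (-1.0, 3.0)
    background_slope: float = 1.0
    background_sd: float = 10.0  # µV
    so_freq: float = 0.8
    so_amp: float = 60.0      # µV
    spindle_rate: float = 1.0     # spindles per learning-cue trial
    spindle_band: tuple[float, float] = (12.0, 15.0)
    spindle_freq: float = 13.0
    spindle_duration: float = 0.75
    spindle_center: float = 1.05  # s after cue onset
    spindle_snr: float = 4.0
    ripple_rate: float = 1.0      # ripples per spindle
    ripple_band: tuple[float, float] = (80.0, 120.0)
    ripple_freq: float = 90.0
    ripple_duration: float = 0.10
    ripple_snr: float = 4.0
    coupling_kappa: float = 2.0
    coupling_mu: float = np.pi
    pattern_snr: float = 1.0
    retrieval_pattern_window: tuple[float, float] = (0.1, 0.6)
    pattern_halfwidth: float = 0.15  # s, around ripple centers in TMR trials
    remembered_frac: float = 0.6
    retrieval_ripple_rate_remembered: float = 1.0   # per trial
    retrieval_ripple_rate_forgotten: float = 0.3
    retrieval_ripple_time: float = 0.45  # s post prompt, +- jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.coupling_kappa < 0:
            raise ValueError("kappa must be >= 0")
        for r in (self.spindle_rate, self.ripple_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.channel_roles is not None and \
                len(self.channel_roles) != self.n_channels:
            raise ValueError("one role per channel required")

    @property
    def roles(self) -> list[str]:
        if self.channel_roles is not None:
            return list(self.channel_roles)
        n_cort = max(1, int(round(self.n_channels * 0.75)))
        n_cort = min(n_cort, self.n_channels - 1) if self.n_channels > 1 else 1
        return ["cortical"] * n_cort + ["mtl"] * (self.n_channels - n_cort)

    @property
    def ch_names(self) -> list[str]:
        names, c, m = [], 0, 0
        for r in self.roles:
            if r == "mtl":
                m += 1
                names.append(f"MTL{m}")
            else:
                c += 1
                names.append(f"C{c}")
        return names

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator injected.

    ``events`` has one row per injected burst with columns ``trial`` (-1 for
    continuous recordings), ``channel``, ``type`` (so/spindle/ripple),
    ``peak_s``, ``onset_s``, ``offset_s``, ``angle`` (ripple phase on the
    concurrent spindle, radians in (-pi, pi]) and ``class``.
    ``trials`` has one row per trial: ``onset_s``, ``class``, ``condition``,
    ``remembered``. ``templates`` maps class name -> channel template.
    """

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    pattern_windows: dict = field(default_factory=dict)
    templates: dict = field(default_factory=dict)

    @property
    def ripple_angles(self) -> np.ndarray:
        if not len(self.events):
            return np.array([])
        rip = self.events[self.events["type"] == "ripple"]
        return rip["angle"].to_numpy(dtype=float)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return w


def _one_over_f(rng: np.random.Generator, n_samples: int, fs: float,
                slope: float, sd: float) -> np.ndarray:
    """One channel of Gaussian 1/f^slope noise, zero mean, SD = ``sd``."""
    white = rng.standard_normal(n_samples)
    if slope == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        gain = np.ones_like(freqs)
        nz = freqs > 0
        gain[nz] = freqs[nz] ** (-slope / 2.0)
        gain[0] = 0.0
        x = np.fft.irfft(spec * gain, n=n_samples)
    x = x - x.mean()
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def make_background(params: SimParams,
                    duration: float | None = None) -> Recording:
    """Gaussian 1/f^slope background, channels x samples, zero mean."""
    dur = duration if duration is not None else params.duration
    if dur is None:
        dur = params.n_trials * params.iti + 4.0
    if dur <= 0:
        raise ValueError("duration must be positive")
    n = int(round(dur * params.fs))
    rng = params.rng()
    data = np.stack([
        _one_over_f(rng, n, params.fs, params.background_slope,
                    params.background_sd)
        for _ in range(params.n_channels)
    ])
    return Recording(data, params.fs, params.ch_names, params.roles)


def _gauss_burst(fs: float, freq: float, duration: float,
                 amp: float, negative_peak: bool = False,
                 env_frac: float = 6.0) -> np.ndarray:
    """Gaussian-windowed sinusoid; carrier peaks (or troughs) at the center.

    The envelope SD is duration/env_frac; 6 gives a compact burst (~1% at
    the edges, used for ripples), 4 a broader one whose supra-threshold
    extent matches the nominal duration (used for spindles).
    """
    n = int(round(duration * fs))
    n += 1 - n % 2  # odd length, exact center sample
    t = (np.arange(n) - n // 2) / fs
    env = np.exp(-0.5 * (t / (duration / env_frac)) ** 2)
    carrier = np.cos(2 * np.pi * freq * t)
    if negative_peak:
        carrier = -carrier
    return amp * env * carrier


def _so_wave(fs: float, freq: float, amp: float) -> tuple[np.ndarray, int]:
    """One SO cycle (down-state then up-state); returns wave and the index
    of the up-state peak, where the spindle is centred."""
    n = int(round(fs / freq))
    t = np.arange(n) / fs
    wave = -amp * np.sin(2 * np.pi * freq * t)  # trough first, peak second
    up_idx = int(np.argmax(wave))
    return wave, up_idx


def _add_burst(data: np.ndarray, ch: int, center_idx: int,
               burst: np.ndarray) -> tuple[int, int]:
    """Add ``burst`` centred at ``center_idx``; returns the clipped span."""
    half = len(burst) // 2
    lo = center_idx - half
    hi = lo + len(burst)
    b0 = max(0, -lo)
    b1 = len(burst) - max(0, hi - data.shape[-1])
    lo, hi = max(lo, 0), min(hi, data.shape[-1])
    data[ch, lo:hi] += burst[b0:b1]
    return lo, hi


def _draw_angles(rng: np.random.Generator, n: int, mu: float,
                 kappa: float) -> np.ndarray:
    if kappa <= 0:
        return _wrap_angle(rng.uniform(-np.pi, np.pi, n))
    if kappa >= _KAPPA_CAP:  # degenerate: all angles exactly mu
        return _wrap_angle(np.full(n, mu))
    return _wrap_angle(rng.vonmises(mu, kappa, n))


def inject_coupled_events(rec: Recording, params: SimParams,
                          rng: np.random.Generator | None = None
                          ) -> tuple[Recording, GroundTruth]:
    """Add SO + spindle bursts (cortical) and phase-coupled ripples (MTL).

    Spindle count is ``round(spindle_rate * duration / iti)`` (one
    opportunity window per nominal trial slot) and ripple count is
    ``round(ripple_rate * n_spindles)`` -- both deterministic in the rates.
    Each ripple is assigned a spindle (round robin) and placed at the time
    where the spindle carrier phase equals an angle drawn from
    von Mises(mu, kappa).
    """
    cort = [i for i, r in enumerate(rec.roles) if r == "cortical"]
    mtl = [i for i, r in enumerate(rec.roles) if r == "mtl"]
    if not cort or not mtl:
        raise ValueError("need at least one cortical and one mtl channel")
    if rng is None:
        rng = params.rng()

    n_spindles = int(round(params.spindle_rate * rec.duration / params.iti))
    if params.coupling_kappa > 0 and n_spindles == 0:
        raise ValueError("kappa > 0 requires spindles to couple ripples to")
    n_ripples = int(round(params.ripple_rate * n_spindles))

    out = rec.copy()
    spin_amp = params.spindle_snr * params.background_sd
    rip_amp = params.ripple_snr * params.background_sd

    # spindle/SO centres on a jittered regular grid, away from the edges
    margin = 1.5
    grid = np.linspace(margin, rec.duration - margin, max(n_spindles, 1),
                       endpoint=True)
    jitter = rng.uniform(-0.2, 0.2, n_spindles)
    centers = np.clip(grid[:n_spindles] + jitter, margin,
                      rec.duration - margin)

    rows = []
    so_wave, so_up = _so_wave(rec.fs, params.so_freq, params.so_amp)
    for t_c in centers:
        c_idx = int(round(t_c * rec.fs))
        so_start = c_idx - so_up
        for ch in cort:
            lo = max(so_start, 0)
            hi = min(so_start + len(so_wave), rec.n_samples)
            out.data[ch, lo:hi] += so_wave[lo - so_start:hi - so_start]
            burst = _gauss_burst(rec.fs, params.spindle_freq,
                                 params.spindle_duration, spin_amp,
                                 env_frac=4.0)
            _add_burst(out.data, ch, c_idx, burst)
        rows.append(dict(trial=-1, channel=rec.ch_names[cort[0]],
                         type="spindle", peak_s=t_c,
                         onset_s=t_c - params.spindle_duration / 2,
                         offset_s=t_c + params.spindle_duration / 2,
                         angle=np.nan, **{"class": ""}))

    angles = _draw_angles(rng, n_ripples, params.coupling_mu,
                          params.coupling_kappa)
    for k in range(n_ripples):
        sp = k % max(n_spindles, 1)
        t_sp = centers[sp]
        # place the ripple where the spindle carrier phase equals the angle
        t_r = t_sp + angles[k] / (2 * np.pi * params.spindle_freq)
        ch = mtl[k % len(mtl)]
        burst = _gauss_burst(rec.fs, params.ripple_freq,
                             params.ripple_duration, rip_amp,
                             negative_peak=True)
        r_idx = int(round(t_r * rec.fs))
        _add_burst(out.data, ch, r_idx, burst)
        rows.append(dict(trial=-1, channel=rec.ch_names[ch], type="ripple",
                         peak_s=r_idx / rec.fs,
                         onset_s=t_r - params.ripple_duration / 2,
                         offset_s=t_r + params.ripple_duration / 2,
                         angle=angles[k], **{"class": ""}))

    gt = GroundTruth(events=pd.DataFrame(rows))
    return out, gt


def _epoch_noise(params: SimParams, n_trials: int, n_times: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Independent 1/f background per trial and channel."""
    data = np.empty((n_trials, params.n_channels, n_times))
    for i in range(n_trials):
        for c in range(params.n_channels):
            data[i, c] = _one_over_f(rng, n_times, params.fs,
                                     params.background_slope,
                                     params.background_sd)
    return data


def _class_templates(params: SimParams,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One fixed multichannel template per class, unit RMS across channels."""
    out = {}
    for cls in ("left", "right"):
        v = rng.standard_normal(params.n_channels)
        v /= np.sqrt(np.mean(v ** 2))
        out[cls] = v
    return out


def inject_class_pattern(ep: EpochSet, labels: np.ndarray,
                         window: tuple[float, float], snr: float,
                         templates: dict[str, np.ndarray],
                         scale: float = 1.0) -> EpochSet:
    """Add the class template inside ``window`` only (bit-exact elsewhere).

    ``snr`` scales the template relative to ``scale`` (the background SD);
    snr = 0 returns an identical copy.
    """
    if window[0] < ep.times[0] - 1e-9 or window[1] > ep.times[-1] + 1e-9:
        raise ValueError(f"pattern window {window} outside epoch time axis")
    out = ep.copy()
    if snr == 0:
        return out
    mask = ep.time_mask(window)
    for i, cls in enumerate(labels):
        if cls in templates:
            out.data[i][:, mask] += snr * scale * templates[cls][:, None]
    return out


def make_task_dataset(params: SimParams
                      ) -> tuple[EpochSet, EpochSet, GroundTruth]:
    """Build matched retrieval and TMR epoch sets with ground truth.

    Retrieval epochs carry the class template in
    ``retrieval_pattern_window`` for remembered trials, plus MTL ripples at
    ~``retrieval_ripple_time`` with a higher rate on remembered trials.
    TMR learning-cue epochs carry a cue-evoked SO + spindle burst on
    cortical channels, von Mises phase-coupled ripples on MTL channels, and
    the class template time-locked to the ripple window; control-cue epochs
    are background only.
    """
    if params.n_trials < 2:
        raise ValueError("need at least 2 trials per class")
    n_per_class = params.n_trials
    if n_per_class % 2 == 1:
        warnings.warn("odd trial count per class; truncating to balance")
        n_per_class -= 1

    rng = params.rng()
    w0, w1 = params.epoch_window
    n_times = int(round((w1 - w0) * params.fs)) + 1
    times = (np.arange(int(round(w0 * params.fs)),
                       int(round(w0 * params.fs)) + n_times)) / params.fs
    cort = [i for i, r in enumerate(params.roles) if r == "cortical"]
    mtl = [i for i, r in enumerate(params.roles) if r == "mtl"]

    templates = _class_templates(params, rng)

    # ---------------- retrieval ----------------
    classes = np.array(["left", "right"]).repeat(n_per_class)
    order = rng.permutation(len(classes))
    classes = classes[order]
    n_ret = len(classes)
    remembered = rng.random(n_ret) < params.remembered_frac
    ret_data = _epoch_noise(params, n_ret, n_times, rng)

    ret_onsets = np.cumsum(
        params.iti + rng.uniform(-params.iti_jitter, params.iti_jitter,
                                 n_ret))
    ev_rows = []
    for i in range(n_ret):
        rate = (params.retrieval_ripple_rate_remembered if remembered[i]
                else params.retrieval_ripple_rate_forgotten)
        n_rip = int(rng.random() < rate) if rate <= 1 else int(round(rate))
        for _ in range(n_rip):
            if not mtl:
                break
            t_r = params.retrieval_ripple_time + rng.normal(0.0, 0.04)
            ch = mtl[i % len(mtl)]
            burst = _gauss_burst(params.fs, params.ripple_freq,
                                 params.ripple_duration,
                                 params.ripple_snr * params.background_sd,
                                 negative_peak=True)
            idx = int(round((t_r - w0) * params.fs))
            _add_burst(ret_data[i], ch, idx, burst)
            ev_rows.append(dict(trial=i, channel=params.ch_names[ch],
                                type="ripple", peak_s=times[idx],
                                onset_s=t_r - params.ripple_duration / 2,
                                offset_s=t_r + params.ripple_duration / 2,
                                angle=np.nan,
                                **{"class": classes[i]},
                                condition="retrieval"))

    ret_labels = pd.DataFrame({
        "class_": classes, "condition": "retrieval",
        "remembered": remembered,
        "session": np.where(np.arange(n_ret) % 2 == 0, "pre", "post"),
        "onset_s": ret_onsets,
    })
    retrieval = EpochSet(ret_data, times, params.fs, params.ch_names,
                         params.roles, ret_labels)
    pat_labels = np.where(remembered, classes, "")
    retrieval = inject_class_pattern(
        retrieval, pat_labels, params.retrieval_pattern_window,
        params.pattern_snr, templates, scale=params.background_sd)

    # ---------------- TMR ----------------
    tmr_classes = np.array(["left", "right", "control"]).repeat(n_per_class)
    tmr_classes = tmr_classes[rng.permutation(len(tmr_classes))]
    n_tmr = len(tmr_classes)
    tmr_data = _epoch_noise(params, n_tmr, n_times, rng)
    tmr_onsets = np.cumsum(
        params.iti + rng.uniform(-params.iti_jitter, params.iti_jitter,
                                 n_tmr))


    so_wave, so_up = _so_wave(params.fs, params.so_freq, params.so_amp)
    learning = tmr_classes != "control"
    n_learn = int(learning.sum())
    n_spindles_per = max(int(round(params.spindle_rate)), 0)
    angles_all = _draw_angles(
        rng, n_learn * n_spindles_per *
        max(int(round(params.ripple_rate)), 0) or 1,
        params.coupling_mu, params.coupling_kappa)
    if params.coupling_kappa > 0 and n_spindles_per == 0 and \
            params.ripple_rate > 0:
        raise ValueError("kappa > 0 requires spindles to couple ripples to")

    a_k = 0
    pattern_windows: dict[int, tuple[float, float]] = {}
    for i in np.flatnonzero(learning):
        cls = tmr_classes[i]
        for _ in range(n_spindles_per):
            t_sp = params.spindle_center + rng.uniform(-0.05, 0.05)
            c_idx = int(round((t_sp - w0) * params.fs))
            for ch in cort:
                so_start = c_idx - so_up
                lo = max(so_start, 0)
                hi = min(so_start + len(so_wave), n_times)
                tmr_data[i, ch, lo:hi] += so_wave[lo - so_start:hi - so_start]
                burst = _gauss_burst(params.fs, params.spindle_freq,
                                     params.spindle_duration,
                                     params.spindle_snr *
                                     params.background_sd, env_frac=4.0)
                _add_burst(tmr_data[i], ch, c_idx, burst)
            ev_rows.append(dict(trial=i, channel=params.ch_names[cort[0]],
                                type="spindle", peak_s=t_sp,
                                onset_s=t_sp - params.spindle_duration / 2,
                                offset_s=t_sp + params.spindle_duration / 2,
                                angle=np.nan, **{"class": cls},
                                condition="tmr"))
            for _ in range(max(int(round(params.ripple_rate)), 0)):
                theta = angles_all[a_k % len(angles_all)]
                a_k += 1
                t_r = t_sp + theta / (2 * np.pi * params.spindle_freq)
                ch = mtl[i % len(mtl)] if mtl else None
                if ch is None:
                    continue
                burst = _gauss_burst(params.fs, params.ripple_freq,
                                     params.ripple_duration,
                                     params.ripple_snr *
                                     params.background_sd,
                                     negative_peak=True)
                r_idx = int(round((t_r - w0) * params.fs))
                _add_burst(tmr_data[i], ch, r_idx, burst)
                ev_rows.append(dict(trial=i, channel=params.ch_names[ch],
                                    type="ripple",
                                    peak_s=(r_idx / params.fs) + w0,
                                    onset_s=t_r - params.ripple_duration / 2,
                                    offset_s=t_r + params.ripple_duration / 2,
                                    angle=theta, **{"class": cls},
                                    condition="tmr"))
                pattern_windows[i] = (t_r - params.pattern_halfwidth,
                                      t_r + params.pattern_halfwidth)

    tmr_labels = pd.DataFrame({
        "class_": tmr_classes, "condition": "tmr",
        "remembered": True, "session": "sleep", "onset_s": tmr_onsets,
    })
    tmr = EpochSet(tmr_data, times, params.fs, params.ch_names,
                   params.roles, tmr_labels)
    # class pattern time-locked to the spindle/ripple window, per trial
    if params.pattern_snr > 0:
        mask_any = np.zeros(n_times, dtype=bool)
        for i, win in pattern_windows.items():
            m = tmr.time_mask(win)
            tmr.data[i][:, m] += (params.pattern_snr * params.background_sd *
                                  templates[tmr_classes[i]][:, None])
            mask_any |= m

    trials = pd.concat([ret_labels.assign(set="retrieval"),
                        tmr_labels.assign(set="tmr")], ignore_index=True)
    events = pd.DataFrame(ev_rows) if ev_rows else pd.DataFrame(
        columns=["trial", "channel", "type", "peak_s", "onset_s",
                 "offset_s", "angle", "class", "condition"])
    gt = GroundTruth(events=events, trials=trials,
                     pattern_windows={
                         "retrieval": params.retrieval_pattern_window,
                         "tmr": pattern_windows},
                     templates=templates)
    return retrieval, tmr, gt
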