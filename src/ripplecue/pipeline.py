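"""End-to-end orchestration of the retrieval and TMR analyses.

``run_retrieval_analysis`` reproduces the awake-retrieval chain: within-task
cross-validated decoding of the cued classes tested against chance with a
cluster permutation test, MTL ripple detection, and the remembered vs
not-remembered peri-event ripple-rate comparison.

``run_tmr_analysis`` runs, in dependency order: TFR contrast of learning vs
control cues -> cluster mask -> median split by SO-spindle cluster power ->
peri-event ripple histograms (high vs low) -> comodulogram with surrogates
-> spindle-phase/ripple coupling with the V test -> split-contrast decoding
-> ripple-locked decoding against its ripple-free surrogate. All stochastic
stages are seeded from the config; every run returns a provenance record
(config hash, seed, package version) alongside the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import decoding as dec
from . import io as rio
from .core import EpochSet
from .coupling import (circular_mean, event_onset_cross_histogram,
                       instantaneous_phase, mi_surrogates,
                       peri_event_histogram, phase_at_events)
from .events import (RippleDetectParams, SpindleDetectParams,
                     detect_events_epochs, detect_ripples, detect_spindles,
                     select_spindle_contact)
from .filters import moving_average
from .preprocess import (baseline_whole_trial, common_average_reference,
                         zscore_across_trials)
from .spectral import (median_split, rectangular_mask, tfr_hanning,
                       trial_power_score, zscore_tfr)
from .stats import cluster_permutation_test, v_test
from .synth import GroundTruth, SimParams, make_background, \
    inject_coupled_events, make_task_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end analyses (defaults follow the study
    conditions the pipeline emulates; see docs/methods.md)."""

    sim: SimParams = field(default_factory=SimParams)
    outdir: str | Path | None = None
    seed: int = 0
    n_components: int = 30
    cv_folds: int = 5
    cv_reps: int = 5
    smooth_width: float = 0.150
    train_window: tuple[float, float] = (-0.5, 1.0)
    test_window: tuple[float, float] = (-0.5, 1.5)
    qualify_window: tuple[float, float] = (0.7, 1.4)
    seg_window: tuple[float, float] = (-0.5, 0.5)
    n_surrogates: int = 100
    n_perm: int = 1000
    decode_fs: float = 100.0  # decoding time grid (post-smoothing decimation)
    tfr_freqs: tuple[float, float] = (4.0, 25.0)
    comod_low: tuple[float, float, float] = (4.0, 20.0, 2.0)   # lo, hi, step
    comod_high: tuple[float, float, float] = (20.0, 130.0, 10.0)
    mi_surrogate_reps: int = 100

    def provenance(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["outdir"] = str(cfg["outdir"])
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {"config_hash": hashlib.sha256(blob.encode()).hexdigest(),
                "seed": self.seed, "version": __version__}


def _decim_factor(fs: float, target: float) -> int:
    return max(1, int(round(fs / target)))


def _smooth_reduced(red: dec.ReducedEpochs, width: float,
                    fs: float) -> dec.ReducedEpochs:
    n = int(round(width * fs))
    n += 1 - n % 2
    if n < 2:
        return red
    out = dec.ReducedEpochs(moving_average(red.scores, n, axis=-1),
                            red.times, red.fs, red.components,
                            red.explained_variance_ratio, red.labels)
    return out


def _condition(ep: EpochSet) -> EpochSet:
    return zscore_across_trials(baseline_whole_trial(
        common_average_reference(ep)))


def run_retrieval_analysis(cfg: PipelineConfig) -> dict:
    """Within-retrieval decoding + retrieval ripple-rate comparison."""
    retrieval, _tmr, gt = make_task_dataset(cfg.sim)
    out: dict = {"provenance": cfg.provenance(), "ground_truth": gt}

    remembered = retrieval.labels["remembered"].to_numpy(dtype=bool)
    ret_dec = retrieval.select_trials(np.flatnonzero(remembered))
    red = dec.pca_reduce(_condition(ret_dec), cfg.n_components)
    red = _smooth_reduced(red, cfg.smooth_width, retrieval.fs)
    red = red.decimate(_decim_factor(retrieval.fs, cfg.decode_fs))
    cv = dec.crossval_timecourse(red, ret_dec.labels["class_"].to_numpy(),
                                 k=cfg.cv_folds, reps=cfg.cv_reps,
                                 seed=cfg.seed)
    out["cv_decoding"] = cv
    out["cv_cluster"] = cluster_permutation_test(
        cv.fold_aucs, reference=0.5, n_perm=cfg.n_perm, seed=cfg.seed)

    mtl = retrieval.channels_by_role("mtl")
    if retrieval.fs < 250:
        logger.warning("scalp-rate data (fs < 250 Hz); ripple analyses "
                       "skipped")
        mtl = []
    if mtl:
        ripples = detect_events_epochs(retrieval, detect_ripples,
                                       channels=mtl)
        out["retrieval_ripples"] = ripples
        if "remembered" in retrieval.labels:
            win = (retrieval.times[0], retrieval.times[-1])
            rates = {}
            for cond, mask in (("remembered", remembered),
                               ("not_remembered", ~remembered)):
                per_ch = []
                for ch in mtl:
                    sel = ripples[ripples["channel"] == ch]
                    per_trial = [
                        sel[sel["trial"] == t]["peak_s"].to_numpy()
                        for t in np.flatnonzero(mask)]
                    centers, rate = peri_event_histogram(
                        per_trial or [np.array([])], win)
                    per_ch.append(rate)
                rates[cond] = np.stack(per_ch)
            out["ripple_rate_bins"] = centers
            out["ripple_rates"] = rates
            if len(mtl) >= 2:
                out["ripple_rate_cluster"] = cluster_permutation_test(
                    rates["remembered"] - rates["not_remembered"],
                    n_perm=cfg.n_perm, seed=cfg.seed)
        else:
            logger.warning("no remembered labels; rate comparison skipped")
    return out


def run_tmr_analysis(cfg: PipelineConfig) -> dict:
    """TFR contrast, coupling and ripple-locked decoding on TMR data."""
    retrieval, tmr, gt = make_task_dataset(cfg.sim)
    out: dict = {"provenance": cfg.provenance(), "ground_truth": gt}

    cort = tmr.channels_by_role("cortical")
    mtl = tmr.channels_by_role("mtl")
    learning = tmr.labels["class_"].isin(["left", "right"]).to_numpy()
    control = ~learning

    # --- 1. TFR learning vs control, cluster mask -----------------------
    freqs = np.arange(cfg.tfr_freqs[0], cfg.tfr_freqs[1] + 1)
    tfr = tfr_hanning(tmr.pick_channels(cort), freqs=freqs)
    tfr = zscore_tfr(tfr, (tmr.times[0], tmr.times[-1]))
    mean_learn = np.nanmean(tfr.power[learning], axis=0)
    mean_ctrl = np.nanmean(tfr.power[control], axis=0)
    contrast = np.nan_to_num(mean_learn - mean_ctrl)  # channels x f x t
    tfr_cluster = cluster_permutation_test(contrast, n_perm=cfg.n_perm,
                                           seed=cfg.seed)
    out["tfr_contrast"] = contrast
    out["tfr_cluster"] = tfr_cluster
    pos = [c for c in tfr_cluster.significant() if c.sign > 0]
    if pos:
        mask = pos[0].mask                        # freqs x times
        logger.info("SO-spindle cluster found (p = %.4f)", pos[0].p)
    else:
        logger.warning("no significant TFR cluster; rectangular fallback")
        mask = rectangular_mask(tfr)
    out["cluster_mask"] = mask

    # --- 2. median split by SO-spindle cluster power --------------------
    scores = np.asarray(trial_power_score(tfr, mask))
    if scores.ndim == 2:       # per-channel scores: average over channels
        scores = np.nanmean(scores, axis=1)
    learn_idx = np.flatnonzero(learning)
    high_rel, low_rel = median_split(scores[learn_idx])
    high_idx, low_idx = learn_idx[high_rel], learn_idx[low_rel]
    out["power_scores"] = scores
    out["split"] = {"high": high_idx, "low": low_idx}

    # --- 3. event detection ---------------------------------------------
    ieeg_mode = tmr.fs >= 250 and bool(mtl)
    if not ieeg_mode:
        logger.warning("no MTL channels at iEEG rate; ripple stages skipped")
    ripples = detect_events_epochs(tmr, detect_ripples, channels=mtl) \
        if ieeg_mode else None
    spindles = detect_events_epochs(tmr, detect_spindles, channels=cort)
    ref_contact = select_spindle_contact(tmr)
    if ripples is not None:
        out["ripples"] = ripples
    out["spindles"] = spindles
    out["spindle_contact"] = ref_contact

    # --- 4. peri-event ripple histograms, high vs low -------------------
    qual = None
    if ieeg_mode:
        win = (tmr.times[0], tmr.times[-1])
        rates = {}
        for cond, idx in (("high", high_idx), ("low", low_idx)):
            per_ch = []
            for ch in mtl:
                sel = ripples[ripples["channel"] == ch]
                per_trial = [sel[sel["trial"] == t]["peak_s"].to_numpy()
                             for t in idx]
                centers, rate = peri_event_histogram(
                    per_trial or [np.array([])], win)
                per_ch.append(rate)
            rates[cond] = np.stack(per_ch)
        out["ripple_rate_bins"] = centers
        out["ripple_rates"] = rates
        if len(mtl) >= 2:
            out["ripple_rate_cluster"] = cluster_permutation_test(
                rates["high"] - rates["low"], n_perm=cfg.n_perm,
                seed=cfg.seed)

        # --- 5. spindle-phase / ripple coupling --------------------------
        spin_ref = spindles[spindles["channel"] == ref_contact]
        qual = []
        for _, r in ripples.iterrows():
            if not (cfg.qualify_window[0] <= r["peak_s"]
                    <= cfg.qualify_window[1]):
                continue
            s = spin_ref[spin_ref["trial"] == r["trial"]]
            if ((s["onset_s"] <= r["peak_s"]) &
                    (s["offset_s"] >= r["peak_s"])).any():
                qual.append(r)
        qual = pd.DataFrame(qual).reset_index(drop=True) if qual \
            else ripples.iloc[:0]
        out["qualifying_ripples"] = qual

        ref_idx = tmr.ch_names.index(ref_contact)
        phase = instantaneous_phase(tmr.data[:, ref_idx], fs=tmr.fs)
        angles = []
        for _, r in qual.iterrows():
            a = phase_at_events(phase[int(r["trial"])], tmr.fs,
                                [r["peak_s"]], t0=tmr.times[0])
            angles.extend(np.atleast_1d(a))
        angles = np.asarray(angles)
        if angles.size >= 2:
            direction, r_len = circular_mean(angles)
            v, p = v_test(angles, np.pi)
            out["phase_stats"] = dict(angles=angles,
                                      mean_direction=direction,
                                      resultant_length=r_len, v=v, p=p)
        else:
            logger.warning("too few coupled ripples for circular stats")
            out["phase_stats"] = None

        if len(ripples) and len(spindles):
            out["onset_histogram"] = event_onset_cross_histogram(
                ripples["onset_s"].to_numpy(),
                spindles["onset_s"].to_numpy())

        # --- 6. comodulogram with surrogates -----------------------------
        if len(qual) >= 3:
            half = int(round(0.5 * tmr.fs))
            ph_segs, am_segs = [], []
            for _, r in qual.iterrows():
                c = int(round((r["peak_s"] - tmr.times[0]) * tmr.fs))
                if c - half < 0 or c + half + 1 > tmr.n_times:
                    continue
                tr = int(r["trial"])
                ph_segs.append(tmr.data[tr, ref_idx,
                                        c - half:c + half + 1])
                am_segs.append(tmr.data[tr,
                                        tmr.ch_names.index(r["channel"]),
                                        c - half:c + half + 1])
            if len(ph_segs) >= 3:
                lo = np.arange(cfg.comod_low[0], cfg.comod_low[1] + 1e-9,
                               cfg.comod_low[2])
                hi = np.arange(cfg.comod_high[0], cfg.comod_high[1] + 1e-9,
                               cfg.comod_high[2])
                out["comodulogram"] = mi_surrogates(
                    np.stack(ph_segs), np.stack(am_segs), tmr.fs,
                    low_freqs=lo, high_freqs=hi, n=cfg.mi_surrogate_reps,
                    seed=cfg.seed)
        if "comodulogram" not in out:
            logger.warning("too few ripple segments for the comodulogram")

    # --- 7. decoding: split contrast and ripple-locked ------------------
    ret_dec = retrieval.select_trials(
        np.flatnonzero(retrieval.labels["remembered"].to_numpy(dtype=bool)))
    red_train, red_test = dec.pca_reduce_pooled(
        _condition(ret_dec), _condition(tmr), cfg.n_components)
    red_train = _smooth_reduced(red_train, cfg.smooth_width, tmr.fs)
    red_test = _smooth_reduced(red_test, cfg.smooth_width, tmr.fs)
    decim = _decim_factor(tmr.fs, cfg.decode_fs)
    red_train = red_train.decimate(decim).crop(cfg.train_window)
    red_test = red_test.decimate(decim)
    y_train = ret_dec.labels["class_"].to_numpy()

    test_learning = red_test.select_trials(learn_idx).crop(cfg.test_window)
    y_learning = tmr.labels["class_"].to_numpy()[learn_idx]
    out["tmr_generalization"] = dec.temporal_generalization(
        red_train, y_train, test_learning, y_learning)

    hi_set = red_test.select_trials(high_idx).crop(cfg.test_window)
    lo_set = red_test.select_trials(low_idx).crop(cfg.test_window)
    out["split_contrast"] = dec.split_condition_contrast(
        red_train, y_train,
        hi_set, tmr.labels["class_"].to_numpy()[high_idx],
        lo_set, tmr.labels["class_"].to_numpy()[low_idx])

    learn_ripples = qual[np.isin(qual["trial"].astype(int), learn_idx)] \
        if qual is not None and len(qual) else None
    if learn_ripples is not None and len(learn_ripples):
        out["ripple_locked"] = dec.ripple_locked_classify(
            red_train, y_train, red_test, learn_ripples,
            qualify_window=cfg.qualify_window, seg_window=cfg.seg_window)
        out["ripple_surrogate"] = dec.surrogate_ripple_baseline(
            red_train, y_train, red_test, learn_ripples,
            n=cfg.n_surrogates, seed=cfg.seed,
            qualify_window=cfg.qualify_window, seg_window=cfg.seg_window)
    else:
        logger.warning("no qualifying learning-trial ripples; "
                       "ripple-locked decoding skipped")

    if cfg.outdir is not None:
        _write_outputs(cfg, out)
    return out


def _write_outputs(cfg: PipelineConfig, out: dict) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "provenance.json").write_text(
        json.dumps(out["provenance"], indent=2))
    for key in ("ripples", "spindles", "qualifying_ripples"):
        if key in out and isinstance(out[key], pd.DataFrame):
            rio.write_table(out[key], outdir / f"{key}.tsv")
    arrays = {}
    for key in ("tfr_contrast", "cluster_mask", "power_scores"):
        if key in out:
            arrays[key] = np.asarray(out[key])
    for key in ("tmr_generalization", "split_contrast", "ripple_locked",
                "ripple_surrogate"):
        if key in out:
            arrays[f"{key}_auc"] = out[key].auc
    if arrays:
        np.savez(outdir / "arrays.npz", **arrays)


def make_fixture(cfg: PipelineConfig, outdir: str | Path | None = None
                 ) -> dict[str, Path]:
    """Write a small synthetic study (EDF + event/label tables) to disk.

    Returns the paths written: a continuous NREM-like recording with
    injected coupled events, its ground-truth event table, and the
    trial/label tables of the matched task dataset.
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = make_background(cfg.sim, duration=cfg.sim.duration or 120.0)
    rec, gt_cont = inject_coupled_events(rec, cfg.sim)
    paths = {"edf": rio.write_edf(rec, outdir / "recording.edf")}

    ev = gt_cont.events.rename(columns={"class": "class_"})
    ev = ev[["onset_s", "channel", "type", "class_"]].copy()
    ev["remembered"] = ""
    paths["events"] = rio.write_table(
        ev.rename(columns={"class_": "class"}), outdir / "ground_truth.tsv")

    _ret, _tmr, gt_task = make_task_dataset(cfg.sim)
    paths["trials"] = rio.write_table(gt_task.trials, outdir / "trials.tsv")
    prov = cfg.provenance()
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
    paths["provenance"] = outdir / "provenance.json"
    return paths
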