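"""Multivariate decoding: LDA over PCA-reduced epochs.

The decoding chain mirrors standard MVPA practice for EEG/iEEG: common
average reference and trial-wise z-scoring upstream, PCA to 30 components
(fitted on the pooled data when two sets must share a space), 150 ms
smoothing, then one shrinkage-regularized LDA per time point scored with
the area under the ROC curve (AUC; chance = 0.5).

Temporal generalization trains a classifier at every training time point
and applies it at every test time point, giving a train-time x test-time
AUC matrix; no cross-validation is needed when train and test sets are
independent. Ripple-locked classification re-epochs the (component-space)
test data around qualifying ripple peaks and contrasts the resulting AUC
map with a surrogate built from ripple-free time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import EpochSet

CHANCE = 0.5


@dataclass
class ReducedEpochs:
    """PCA component scores, trials x components x time."""

    scores: np.ndarray
    times: np.ndarray
    fs: float
    components: np.ndarray          # components x channels (shared-space id)
    explained_variance_ratio: np.ndarray
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return self.scores.shape[0]

    def same_space(self, other: "ReducedEpochs") -> bool:
        return (self.components.shape == other.components.shape and
                np.allclose(self.components, other.components))

    def select_trials(self, index) -> "ReducedEpochs":
        index = np.asarray(index)
        lab = self.labels.iloc[index].reset_index(drop=True) \
            if len(self.labels) else self.labels
        return ReducedEpochs(self.scores[index].copy(), self.times, self.fs,
                             self.components, self.explained_variance_ratio,
                             lab)

    def crop(self, window: tuple[float, float]) -> "ReducedEpochs":
        m = (self.times >= window[0]) & (self.times <= window[1])
        return ReducedEpochs(self.scores[:, :, m].copy(),
                             self.times[m].copy(), self.fs, self.components,
                             self.explained_variance_ratio,
                             self.labels.copy())

    def decimate(self, factor: int) -> "ReducedEpochs":
        """Keep every ``factor``-th time sample (apply after smoothing)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return self
        return ReducedEpochs(self.scores[:, :, ::factor].copy(),
                             self.times[::factor].copy(), self.fs / factor,
                             self.components, self.explained_variance_ratio,
                             self.labels.copy())


@dataclass
class DecodingResult:
    """AUC over time (1 x times) or train-time x test-time."""

    auc: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray
    chance: float = CHANCE
    n_folds: int = 0
    n_reps: int = 0
    fold_aucs: np.ndarray | None = None  # folds*reps x ... for variance


def _fit_pca(data: np.ndarray, n: int) -> PCA:
    """Fit PCA with channels as variables, trial x time as observations."""
    n_tr, n_ch, n_t = data.shape
    X = np.transpose(data, (0, 2, 1)).reshape(n_tr * n_t, n_ch)
    n_eff = min(n, n_ch)
    if n_eff < n:
        warnings.warn(f"n_components clamped from {n} to {n_ch} (channel "
                      "count)")
    pca = PCA(n_components=n_eff)
    pca.fit(X)
    return pca

def _transform(pca: PCA, data: np.ndarray) -> np.ndarray:
    n_tr, n_ch, n_t = data.shape
    X = np.transpose(data, (0, 2, 1)).reshape(n_tr * n_t, n_ch)
    S = pca.transform(X)
    return np.transpose(S.reshape(n_tr, n_t, -1), (0, 2, 1))


def pca_reduce(ep: EpochSet, n: int = 30) -> ReducedEpochs:
    """PCA on the pooled (trial x time, channel) matrix of one epoch set."""
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials")
    pca = _fit_pca(ep.data, n)
    return ReducedEpochs(_transform(pca, ep.data), ep.times.copy(), ep.fs,
                         pca.components_.copy(),
                         pca.explained_variance_ratio_.copy(),
                         ep.labels.copy())


def pca_reduce_pooled(ep_a: EpochSet, ep_b: EpochSet, n: int = 30
                      ) -> tuple[ReducedEpochs, ReducedEpochs]:
    """Fit one PCA on both sets pooled; both outputs share the space."""
    if list(ep_a.ch_names) != list(ep_b.ch_names):
        raise ValueError("epoch sets must share channels")
    stacked = np.concatenate([
        np.transpose(ep_a.data, (0, 2, 1)).reshape(-1, ep_a.n_channels),
        np.transpose(ep_b.data, (0, 2, 1)).reshape(-1, ep_b.n_channels)])
    n_eff = min(n, ep_a.n_channels)
    if n_eff < n:
        warnings.warn(f"n_components clamped from {n} to {ep_a.n_channels}")
    pca = PCA(n_components=n_eff)
    pca.fit(stacked)
    red = []
    for ep in (ep_a, ep_b):
        red.append(ReducedEpochs(_transform(pca, ep.data), ep.times.copy(),
                                 ep.fs, pca.components_.copy(),
                                 pca.explained_variance_ratio_.copy(),
                                 ep.labels.copy()))
    return red[0], red[1]


def train_lda(X: np.ndarray, y: np.ndarray,
              shrinkage: str | float = "auto") -> LinearDiscriminantAnalysis:
    """Shrinkage-regularized LDA (lsqr solver)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(X, y)
    return clf


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """P(random positive score > random negative score); ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    pos = y == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    r = rankdata(scores)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_rows(score_rows: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (cases x trials) score matrix."""
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    r = rankdata(score_rows, axis=-1)
    return (r[..., pos].sum(axis=-1) - n_pos * (n_pos + 1) / 2) / \
        (n_pos * n_neg)


def _binary(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    return y, y == classes[1]


def crossval_timecourse(red: ReducedEpochs, labels=None, k: int = 5,
                        reps: int = 5, seed: int | None = None,
                        shrinkage: str | float = "auto") -> DecodingResult:
    """Stratified k-fold CV AUC per time point, averaged over folds and
    repetitions (fold assignment is seeded and reproducible)."""
    y = np.asarray(labels if labels is not None
                   else red.labels["class_"].to_numpy())
    y, _ = _binary(y)
    counts = np.unique(y, return_counts=True)[1]
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(f"folds reduced from {k} to {k_eff} (class size)")
    if k_eff < 2:
        raise ValueError("need at least 2 trials per class")
    rng = np.random.default_rng(seed)
    n_t = red.scores.shape[2]
    fold_aucs = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
            row = np.empty(n_t)
            _, pos_te = _binary(y[te_idx])
            for t in range(n_t):
                clf = train_lda(red.scores[tr_idx, :, t], y[tr_idx],
                                shrinkage)
                s = clf.decision_function(red.scores[te_idx, :, t])
                row[t] = _auc_rows(s[None, :], pos_te)[0]
            fold_aucs.append(row)
    fold_aucs = np.stack(fold_aucs)
    return DecodingResult(fold_aucs.mean(axis=0)[None, :],
                          train_times=red.times, test_times=red.times,
                          n_folds=k_eff, n_reps=reps, fold_aucs=fold_aucs)


def _train_weight_stack(train: ReducedEpochs, y: np.ndarray,
                        shrinkage) -> tuple[np.ndarray, np.ndarray]:
    """One LDA per training time point; returns (times x comp) weights and
    intercepts."""
    n_t = train.scores.shape[2]
    W = np.empty((n_t, train.scores.shape[1]))
    b = np.empty(n_t)
    for t in range(n_t):
        clf = train_lda(train.scores[:, :, t], y, shrinkage)
        W[t] = clf.coef_[0]
        b[t] = clf.intercept_[0]
    return W, b


def _generalize(W: np.ndarray, b: np.ndarray, test_scores: np.ndarray,
                pos: np.ndarray) -> np.ndarray:
    """AUC matrix (train times x test times) from stacked weights."""
    # scores: trials x comp x test_t -> (train_t x test_t x trials)
    s = np.einsum("kc,ict->kti", W, test_scores) + b[:, None, None]
    return _auc_rows(s, pos)


def temporal_generalization(train: ReducedEpochs, train_labels,
                            test: ReducedEpochs, test_labels,
                            shrinkage: str | float = "auto"
                            ) -> DecodingResult:
    """Train at every training time, test at every test time (AUC matrix).

    Both inputs must share the PCA component space (fit it pooled).
    """
    if not train.same_space(test):
        raise ValueError("train and test must share the PCA space")
    y_tr, _ = _binary(np.asarray(train_labels))
    y_te, pos_te = _binary(np.asarray(test_labels))
    W, b = _train_weight_stack(train, y_tr, shrinkage)
    auc_mat = _generalize(W, b, test.scores, pos_te)
    return DecodingResult(auc_mat, train_times=train.times,
                          test_times=test.times)


def split_condition_contrast(train: ReducedEpochs, train_labels,
                             test_high: ReducedEpochs, high_labels,
                             test_low: ReducedEpochs, low_labels,
                             shrinkage: str | float = "auto"
                             ) -> DecodingResult:
    """AUC(high split) - AUC(low split), element-wise."""
    if test_high.n_trials == 0 or test_low.n_trials == 0:
        raise ValueError("both splits must be non-empty")
    hi = temporal_generalization(train, train_labels, test_high, high_labels,
                                 shrinkage)
    lo = temporal_generalization(train, train_labels, test_low, low_labels,
                                 shrinkage)
    return DecodingResult(hi.auc - lo.auc, train_times=hi.train_times,
                          test_times=hi.test_times, chance=0.0)


def _qualifying_ripples(ripples: pd.DataFrame,
                        spindles: pd.DataFrame | None,
                        window: tuple[float, float],
                        spindle_channel: str | None) -> pd.DataFrame:
    """Ripples whose peak lies in ``window`` post-cue and (when a spindle
    table is given) inside a spindle's extent on the reference contact."""
    q = ripples[(ripples["peak_s"] >= window[0]) &
                (ripples["peak_s"] <= window[1])].copy()
    if spindles is not None and len(spindles):
        sp = spindles
        if spindle_channel is not None:
            sp = sp[sp["channel"] == spindle_channel]
        keep = []
        for _, r in q.iterrows():
            s = sp[sp["trial"] == r["trial"]] if "trial" in sp.columns else sp
            keep.append(bool(((s["onset_s"] <= r["peak_s"]) &
                              (s["offset_s"] >= r["peak_s"])).any()))
        q = q[np.asarray(keep, dtype=bool)] if len(q) else q
    return q.reset_index(drop=True)


def _ripple_locked_segments(test: ReducedEpochs, centers: pd.DataFrame,
                            window: tuple[float, float]
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-epoch component scores around per-trial center times."""
    fs = test.fs
    t0 = test.times[0]
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    rel_times = np.arange(i0, i1 + 1) / fs
    n_t = test.scores.shape[2]
    segs, labs = [], []
    for _, r in centers.iterrows():
        tr = int(r["trial"])
        c = int(round((r["peak_s"] - t0) * fs))
        lo, hi = c + i0, c + i0 + len(rel_times)
        if lo < 0 or hi > n_t:
            continue
        segs.append(test.scores[tr, :, lo:hi])
        labs.append(test.labels["class_"].iloc[tr]
                    if len(test.labels) else r.get("class", ""))
    if not segs:
        raise ValueError("no segments fully inside the epochs")
    return np.stack(segs), np.asarray(labs), rel_times


def ripple_locked_classify(train: ReducedEpochs, train_labels,
                           test: ReducedEpochs, ripples: pd.DataFrame,
                           spindles: pd.DataFrame | None = None,
                           spindle_channel: str | None = None,
                           qualify_window: tuple[float, float] = (0.7, 1.4),
                           seg_window: tuple[float, float] = (-0.5, 0.5),
                           shrinkage: str | float = "auto"
                           ) -> DecodingResult:
    """Apply retrieval-trained classifiers to ripple-centered segments.

    Qualifying ripples peak inside ``qualify_window`` after the cue and,
    when a spindle table is supplied, inside a detected spindle's extent on
    the reference cortical contact. Returns AUC over
    (train time x ripple-locked time).
    """
    if not train.same_space(test):
        raise ValueError("train and test must share the PCA space")
    q = _qualifying_ripples(ripples, spindles, qualify_window,
                            spindle_channel)
    if not len(q):
        raise ValueError(f"zero qualifying ripples (of {len(ripples)} "
                         "detected)")
    segs, labs, rel_times = _ripple_locked_segments(test, q, seg_window)
    y_tr, _ = _binary(np.asarray(train_labels))
    labs, pos = _binary(labs)
    W, b = _train_weight_stack(train, y_tr, shrinkage)
    auc_mat = _generalize(W, b, segs, pos)
    return DecodingResult(auc_mat, train_times=train.times,
                          test_times=rel_times)


def surrogate_ripple_baseline(train: ReducedEpochs, train_labels,
                              test: ReducedEpochs, ripples: pd.DataFrame,
                              n: int = 100, seed: int | None = None,
                              qualify_window: tuple[float, float] = (0.7, 1.4),
                              seg_window: tuple[float, float] = (-0.5, 0.5),
                              exclusion: float = 0.100,
                              shrinkage: str | float = "auto"
                              ) -> DecodingResult:
    """Ripple-free surrogate for :func:`ripple_locked_classify`.

    Each repetition draws as many random time points (uniform in the
    qualifying window, >= ``exclusion`` s from any ripple peak, in the same
    trials) as there are qualifying ripples, decodes them identically, and
    the ``n`` AUC maps are averaged.
    """
    if not train.same_space(test):
        raise ValueError("train and test must share the PCA space")
    rng = np.random.default_rng(seed)
    q = _qualifying_ripples(ripples, None, qualify_window, None)
    if not len(q):
        raise ValueError("zero qualifying ripples")
    y_tr, _ = _binary(np.asarray(train_labels))
    W, b = _train_weight_stack(train, y_tr, shrinkage)

    ripple_peaks = {tr: g["peak_s"].to_numpy()
                    for tr, g in ripples.groupby("trial")}
    acc = None
    for _ in range(n):
        rows = []
        for _, r in q.iterrows():
            tr = int(r["trial"])
            peaks = ripple_peaks.get(tr, np.array([]))
            for _attempt in range(200):
                t = rng.uniform(*qualify_window)
                if peaks.size == 0 or np.min(np.abs(peaks - t)) >= exclusion:
                    rows.append(dict(trial=tr, peak_s=t))
                    break
            else:
                raise ValueError("qualifying window saturated by ripples")
        centers = pd.DataFrame(rows)
        segs, labs, rel_times = _ripple_locked_segments(test, centers,
                                                        seg_window)
        labs, pos = _binary(labs)
        m = _generalize(W, b, segs, pos)
        acc = m if acc is None else acc + m
    return DecodingResult(acc / n, train_times=train.times,
                          test_times=rel_times, n_reps=n)
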