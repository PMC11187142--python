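"""LDA/PCA decoding: AUC semantics, cross-validation, generalization and
ripple-locked classification on constructed data."""

import numpy as np
import pandas as pd
import pytest

from ripplecue.core import EpochSet
from ripplecue.decoding import (ReducedEpochs, auc, crossval_timecourse,
                                pca_reduce, pca_reduce_pooled,
                                ripple_locked_classify,
                                split_condition_contrast,
                                surrogate_ripple_baseline,
                                temporal_generalization, train_lda)


def brute_force_auc(scores, y):
    classes = np.unique(y)
    pos = np.asarray(scores)[y == classes[1]]
    neg = np.asarray(scores)[y == classes[0]]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _epochs(data, fs=100.0, labels=None, t0=-0.5):
    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[2]) / fs
    names = [f"ch{i}" for i in range(data.shape[1])]
    lab = pd.DataFrame({"class_": labels}) if labels is not None \
        else pd.DataFrame(index=range(data.shape[0]))
    return EpochSet(data, times, fs, names, ["cortical"] * data.shape[1],
                    lab)


def _patterned(rng, n_per_class=20, n_ch=10, n_t=100, fs=100.0,
               window=(0.0, 0.3), snr=5.0, t0=-0.5):
    """Two-class data with a fixed channel pattern inside ``window``."""
    y = np.array(["left", "right"]).repeat(n_per_class)
    data = rng.standard_normal((2 * n_per_class, n_ch, n_t))
    templates = {"left": rng.standard_normal(n_ch),
                 "right": rng.standard_normal(n_ch)}
    times = t0 + np.arange(n_t) / fs
    m = (times >= window[0]) & (times <= window[1])
    for i, cls in enumerate(y):
        data[i][:, m] += snr * templates[cls][:, None]
    return _epochs(data, fs, labels=y, t0=t0), y


class TestPcaReduce:
    def test_component_count_clamped_with_warning(self, rng):
        ep = _epochs(rng.standard_normal((8, 3, 50)))
        with pytest.warns(UserWarning, match="clamp"):
            red = pca_reduce(ep, n=30)
        assert red.scores.shape[1] == 3

    def test_two_source_mixture_concentrates_variance(self, rng):
        s = rng.standard_normal((10, 2, 200))
        mix = rng.standard_normal((6, 2))
        data = np.einsum("cq,kqt->kct", mix, s)
        red = pca_reduce(_epochs(data), n=6)
        assert red.explained_variance_ratio[:2].sum() > 0.99

    def test_full_reconstruction(self, rng):
        ep = _epochs(rng.standard_normal((5, 4, 30)))
        red = pca_reduce(ep, n=4)
        n_tr, n_ch, n_t = ep.data.shape
        X = np.transpose(ep.data, (0, 2, 1)).reshape(-1, n_ch)
        S = np.transpose(red.scores, (0, 2, 1)).reshape(-1, 4)
        recon = S @ red.components + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_variance_shares_non_increasing(self, rng):
        red = pca_reduce(_epochs(rng.standard_normal((8, 6, 40))), n=6)
        assert np.all(np.diff(red.explained_variance_ratio) <= 1e-12)


class TestTrainLda:
    def test_separable_clouds_reach_perfect_training_auc(self, rng):
        X = np.vstack([rng.standard_normal((20, 4)) - 5,
                       rng.standard_normal((20, 4)) + 5])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_lda(X, y)
        assert auc(clf.decision_function(X), y) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.standard_normal((200, 6))
        y = rng.permutation([0] * 100 + [1] * 100)
        clf = train_lda(X, y)
        assert abs(auc(clf.decision_function(X), y) - 0.5) < 0.1

    def test_trial_duplication_preserves_direction(self, rng):
        X = rng.standard_normal((40, 5)) + \
            np.outer(np.r_[np.zeros(20), np.ones(20)], np.ones(5))
        y = np.array([0] * 20 + [1] * 20)
        # fixed shrinkage: duplication leaves mean and covariance unchanged
        w1 = train_lda(X, y, shrinkage=0.1).coef_[0]
        w2 = train_lda(np.vstack([X, X]), np.r_[y, y], shrinkage=0.1).coef_[0]
        cos = w1 @ w2 / np.linalg.norm(w1) / np.linalg.norm(w2)
        assert cos > 0.999

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_lda(rng.standard_normal((10, 3)), np.zeros(10))


class TestAuc:
    @pytest.mark.parametrize("scores,y,expected", [
        ([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5], [1, 0], 0.5),
        ([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], 0.75),
    ])
    def test_known_cases(self, scores, y, expected):
        assert auc(np.array(scores), np.array(y)) == expected

    def test_matches_concordant_pair_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 100))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            y = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            assert auc(scores, y) == brute_force_auc(scores, y)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestCrossvalTimecourse:
    def test_pattern_window_recovered(self, rng):
        ep, y = _patterned(rng)
        red = pca_reduce(ep, n=10)
        res = crossval_timecourse(red, y, seed=0, reps=2)
        inside = (res.test_times >= 0.0) & (res.test_times <= 0.3)
        outside = res.test_times < -0.1
        assert res.auc[0, inside].mean() > 0.9
        assert abs(res.auc[0, outside].mean() - 0.5) < 0.15

    def test_shuffled_labels_centered_on_chance(self, rng):
        ep, y = _patterned(rng, n_per_class=50, snr=3.0)
        y_sh = rng.permutation(y)
        red = pca_reduce(ep, n=10)
        res = crossval_timecourse(red, y_sh, seed=1, reps=2)
        assert abs(res.auc.mean() - 0.5) < 0.05

    def test_seeded_folds_reproduce(self, rng):
        ep, y = _patterned(rng, n_per_class=10)
        red = pca_reduce(ep, n=5)
        a = crossval_timecourse(red, y, seed=7, reps=2)
        b = crossval_timecourse(red, y, seed=7, reps=2)
        np.testing.assert_array_equal(a.fold_aucs, b.fold_aucs)

    def test_fold_count_reduced_with_warning(self, rng):
        ep, y = _patterned(rng, n_per_class=3)
        red = pca_reduce(ep, n=5)
        with pytest.warns(UserWarning, match="folds"):
            crossval_timecourse(red, y, k=5, reps=1, seed=0)


class TestTemporalGeneralization:
    def test_shared_pattern_generalizes_across_time(self, rng):
        n_ch, tmpl = 8, rng.standard_normal(8)
        tr = rng.standard_normal((40, n_ch, 60))
        te = rng.standard_normal((40, n_ch, 80))
        y = np.array(["a", "b"]).repeat(20)
        sgn = np.where(y == "a", 1.0, -1.0)
        # train pattern at 0.2 s (idx 70->20), test pattern at 1.0 s
        tr[:, :, 18:23] += 4 * sgn[:, None, None] * tmpl[None, :, None]
        te[:, :, 45:50] += 4 * sgn[:, None, None] * tmpl[None, :, None]
        red_tr, red_te = pca_reduce_pooled(
            _epochs(tr, fs=40.0, labels=y), _epochs(te, fs=40.0, labels=y),
            n=8)
        res = temporal_generalization(red_tr, y, red_te, y)
        assert res.auc[20, 47] > 0.9
        assert abs(res.auc[5, 5] - 0.5) < 0.2

    def test_label_swap_flips_auc(self, rng):
        ep, y = _patterned(rng, n_per_class=15, n_t=40)
        red = pca_reduce(ep, n=6)
        res = temporal_generalization(red, y, red, y)
        y_sw = np.where(y == "left", "zright", "aleft")
        res_sw = temporal_generalization(red, y, red, y_sw)
        np.testing.assert_allclose(res_sw.auc, 1.0 - res.auc, atol=1e-12)

    def test_mismatched_spaces_rejected(self, rng):
        ep1, y = _patterned(rng, n_per_class=5, n_t=20)
        ep2, _ = _patterned(rng, n_per_class=5, n_t=20)
        r1, r2 = pca_reduce(ep1, n=4), pca_reduce(ep2, n=4)
        with pytest.raises(ValueError):
            temporal_generalization(r1, y, r2, y)


class TestSplitContrast:
    def test_identical_splits_zero_contrast(self, rng):
        ep, y = _patterned(rng, n_per_class=10, n_t=30)
        red = pca_reduce(ep, n=5)
        res = split_condition_contrast(red, y, red, y, red, y)
        np.testing.assert_allclose(res.auc, 0.0, atol=1e-12)

    def test_antisymmetric_under_swap(self, rng):
        ep, y = _patterned(rng, n_per_class=10, n_t=30)
        red = pca_reduce(ep, n=5)
        hi = red.select_trials(np.arange(0, 20, 2))
        lo = red.select_trials(np.arange(1, 20, 2))
        a = split_condition_contrast(red, y, hi, y[0:20:2], lo, y[1:20:2])
        b = split_condition_contrast(red, y, lo, y[1:20:2], hi, y[0:20:2])
        np.testing.assert_allclose(a.auc, -b.auc, atol=1e-12)


class TestRippleLocked:
    def _setup(self, rng, locked=True):
        """TMR-like epochs with per-trial 'ripples'; the class pattern is
        injected at (or away from) the ripple time."""
        fs, n_per = 100.0, 15
        n_t = 250  # [-0.5, 2.0) s
        tmpl = rng.standard_normal(6)
        y = np.array(["left", "right"]).repeat(n_per)
        sgn = np.where(y == "left", 1.0, -1.0)
        tr_data = rng.standard_normal((2 * n_per, 6, 80))  # [-0.5, 0.3)
        tr_data[:, :, 55:70] += 4 * sgn[:, None, None] * tmpl[None, :, None]
        te_data = rng.standard_normal((2 * n_per, 6, n_t))
        peaks = rng.uniform(0.8, 1.3, 2 * n_per)
        rows = []
        for i, pk in enumerate(peaks):
            c = int(round((pk + 0.5) * fs))
            if locked:
                te_data[i, :, c - 7:c + 8] += \
                    4 * sgn[i] * tmpl[:, None]
            else:
                te_data[i, :, 20:35] += 4 * sgn[i] * tmpl[:, None]
            rows.append(dict(trial=i, peak_s=pk, channel="m",
                             onset_s=pk - 0.05, offset_s=pk + 0.05))
        ripples = pd.DataFrame(rows)
        train = _epochs(tr_data, fs, labels=y)
        test = _epochs(te_data, fs, labels=y)
        red_tr, red_te = pca_reduce_pooled(train, test, n=6)
        return red_tr.crop((0.0, 0.25)), y, red_te, ripples

    def test_locked_pattern_decodable_at_lag_zero(self, rng):
        red_tr, y, red_te, ripples = self._setup(rng, locked=True)
        res = ripple_locked_classify(red_tr, y, red_te, ripples,
                                     seg_window=(-0.4, 0.4))
        j0 = np.argmin(np.abs(res.test_times))
        assert res.auc[:, j0].max() > 0.8

    def test_unlocked_pattern_near_chance(self, rng):
        red_tr, y, red_te, ripples = self._setup(rng, locked=False)
        res = ripple_locked_classify(red_tr, y, red_te, ripples,
                                     seg_window=(-0.4, 0.4))
        j0 = np.argmin(np.abs(res.test_times))
        assert abs(res.auc[:, j0].mean() - 0.5) < 0.15

    def test_no_qualifying_ripples_rejected(self, rng):
        red_tr, y, red_te, ripples = self._setup(rng)
        far = ripples.assign(peak_s=ripples["peak_s"] + 10.0)
        with pytest.raises(ValueError, match="qualifying"):
            ripple_locked_classify(red_tr, y, red_te, far)

    def test_surrogate_below_locked_performance(self, rng):
        red_tr, y, red_te, ripples = self._setup(rng, locked=True)
        obs = ripple_locked_classify(red_tr, y, red_te, ripples,
                                     seg_window=(-0.3, 0.3))
        sur = surrogate_ripple_baseline(red_tr, y, red_te, ripples, n=10,
                                        seed=0, seg_window=(-0.3, 0.3))
        j0 = np.argmin(np.abs(obs.test_times))
        assert obs.auc[:, j0].max() > sur.auc[:, j0].max()

    def test_surrogate_seeded_determinism(self, rng):
        red_tr, y, red_te, ripples = self._setup(rng)
        a = surrogate_ripple_baseline(red_tr, y, red_te, ripples, n=5,
                                      seed=3, seg_window=(-0.3, 0.3))
        b = surrogate_ripple_baseline(red_tr, y, red_te, ripples, n=5,
                                      seed=3, seg_window=(-0.3, 0.3))
        np.testing.assert_array_equal(a.auc, b.auc)


def test_reduced_epochs_decimate():
    scores = np.arange(2 * 3 * 10, dtype=float).reshape(2, 3, 10)
    red = ReducedEpochs(scores, np.arange(10) / 10.0, 10.0,
                        np.eye(3), np.ones(3) / 3)
    out = red.decimate(2)
    assert out.scores.shape == (2, 3, 5)
    np.testing.assert_allclose(out.times, np.arange(5) / 5.0)
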