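"""Phase-amplitude coupling, circular summaries and event-timing
histograms."""

import numpy as np
import pytest

from ripplecue.coupling import (circular_mean, comodulogram,
                                event_onset_cross_histogram,
                                instantaneous_phase, mi_surrogates,
                                modulation_index, peri_event_histogram,
                                phase_at_events)


def brute_force_mi(phase, amp, n_bins=18):
    """Independent oracle: explicit bin loop + KL formula."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = np.zeros(n_bins)
    for k in range(n_bins):
        if k == n_bins - 1:
            sel = (phase >= edges[k]) & (phase <= edges[k + 1])
        else:
            sel = (phase >= edges[k]) & (phase < edges[k + 1])
        if sel.any():
            means[k] = amp[sel].mean()
    p = means / means.sum()
    kl = np.log(n_bins) + sum(pi * np.log(pi) for pi in p if pi > 0)
    return kl / np.log(n_bins)


class TestInstantaneousPhase:
    def test_zero_at_filtered_peak(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs - 1.0
        ph = instantaneous_phase(np.cos(2 * np.pi * 13 * t), fs=fs)
        assert abs(ph[1000]) < 0.1  # t = 0 is a carrier peak

    def test_pi_at_filtered_trough(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs - 1.0
        ph = instantaneous_phase(-np.cos(2 * np.pi * 13 * t), fs=fs)
        assert abs(abs(ph[1000]) - np.pi) < 0.1

    def test_phase_velocity_matches_carrier(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        ph = instantaneous_phase(np.cos(2 * np.pi * 13 * t), fs=fs)
        mid = slice(1000, 3000)
        rate = np.diff(np.unwrap(ph[mid])).mean() * fs
        assert abs(rate - 2 * np.pi * 13) < 0.5

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100), band=(80, 120), fs=200.0)


class TestModulationIndex:
    def test_constant_amplitude_gives_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 10000)
        assert modulation_index(ph, np.ones(10000)) == 0.0

    def test_single_bin_mass_gives_one(self):
        assert modulation_index(np.full(50, 0.1), np.ones(50)) == 1.0

    def test_two_equal_bins_closed_form(self):
        w = 2 * np.pi / 18
        ph = np.concatenate([np.full(40, -np.pi + 0.5 * w),
                             np.full(40, -np.pi + 1.5 * w)])
        mi = modulation_index(ph, np.ones(80))
        assert abs(mi - np.log(9) / np.log(18)) < 1e-12

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            ph = rng.uniform(-np.pi, np.pi, 500)
            amp = rng.random(500)
            assert abs(modulation_index(ph, amp) -
                       brute_force_mi(ph, amp)) < 1e-12

    def test_all_zero_amplitude_warns_zero(self):
        with pytest.warns(UserWarning):
            assert modulation_index(np.zeros(10), np.zeros(10)) == 0.0

    def test_invariant_to_amplitude_rescaling(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 1000)
        amp = rng.random(1000)
        assert abs(modulation_index(ph, amp) -
                   modulation_index(ph, 7.3 * amp)) < 1e-12


class TestComodulogram:
    def _coupled(self, rng, fs=500.0, f_low=14.0, f_high=90.0, depth=1.0,
                 T=30.0):
        t = np.arange(int(T * fs)) / fs
        slow = np.cos(2 * np.pi * f_low * t)
        fast = (1 + depth * slow) / 2 * np.cos(2 * np.pi * f_high * t)
        x = slow + 0.5 * rng.standard_normal(len(t))
        y = fast + 0.5 * rng.standard_normal(len(t))
        return x, y

    def test_peak_localization(self, rng):
        fs = 500.0
        x, y = self._coupled(rng)
        mi = comodulogram(x, y, fs)
        i, j = np.unravel_index(np.argmax(mi.mi), mi.mi.shape)
        assert abs(mi.low_freqs[i] - 14.0) <= 2.0
        assert abs(mi.high_freqs[j] - 90.0) <= 10.0

    def test_mi_increases_with_modulation_depth(self, rng):
        fs = 500.0
        x1, y1 = self._coupled(rng, depth=0.4)
        x2, y2 = self._coupled(rng, depth=0.8)
        lo, hi = [14.0], [90.0]
        m1 = comodulogram(x1, y1, fs, lo, hi).mi[0, 0]
        m2 = comodulogram(x2, y2, fs, lo, hi).mi[0, 0]
        assert m2 > m1

    def test_values_in_unit_interval(self, rng):
        mi = comodulogram(rng.standard_normal(4000),
                          rng.standard_normal(4000), 500.0,
                          low_freqs=[6, 10], high_freqs=[40, 80])
        assert np.all((mi.mi >= 0) & (mi.mi <= 1))


class TestMiSurrogates:
    def test_seeded_run_repeats_exactly(self, rng):
        ph = rng.standard_normal((5, 400))
        am = rng.standard_normal((5, 400))
        a = mi_surrogates(ph, am, 500.0, [10], [80], n=10, seed=3)
        b = mi_surrogates(ph, am, 500.0, [10], [80], n=10, seed=3)
        np.testing.assert_array_equal(a.surrogate_mi, b.surrogate_mi)

    def test_identical_trials_make_shuffling_inert(self, rng):
        one = rng.standard_normal(400)
        ph = np.tile(one, (4, 1))
        am = np.tile(rng.standard_normal(400), (4, 1))
        res = mi_surrogates(ph, am, 500.0, [10], [80], n=20, seed=0)
        np.testing.assert_allclose(
            res.surrogate_mi, np.broadcast_to(res.mi, res.surrogate_mi.shape),
            atol=1e-12)

    def test_strong_coupling_beats_surrogates(self):
        fs = 500.0
        n_ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.arange(int(1.0 * fs)) / fs
            trials_ph, trials_am = [], []
            for k in range(12):
                phi = rng.uniform(0, 2 * np.pi)
                slow = np.cos(2 * np.pi * 13 * t + phi)
                fast = (1 + slow) / 2 * np.cos(2 * np.pi * 90 * t)
                trials_ph.append(slow + 0.2 * rng.standard_normal(len(t)))
                trials_am.append(fast + 0.2 * rng.standard_normal(len(t)))
            res = mi_surrogates(np.stack(trials_ph), np.stack(trials_am),
                                fs, [13], [90], n=50, seed=seed)
            n_ok += res.mi[0, 0] > res.surrogate_mi[:, 0, 0].max()
        assert n_ok >= 9

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            mi_surrogates(rng.standard_normal((2, 100)),
                          rng.standard_normal((2, 100)), 500.0, [10], [80])


class TestPhaseAtEvents:
    def test_events_at_troughs_read_pi(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        ph = instantaneous_phase(np.cos(2 * np.pi * 13 * t), fs=fs)
        troughs = (np.arange(10) + 0.5) / 13.0 + 1.0
        ang = phase_at_events(ph, fs, troughs)
        assert np.all(np.abs(np.abs(ang) - np.pi) < np.deg2rad(10))

    def test_event_at_peak_reads_zero(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        ph = instantaneous_phase(np.cos(2 * np.pi * 13 * t), fs=fs)
        ang = phase_at_events(ph, fs, [2.0 / 13.0 * 13])  # integer cycles
        assert abs(ang[0]) < np.deg2rad(10)

    def test_empty_events_give_empty_output(self):
        out = phase_at_events(np.zeros(100), 100.0, [], window=(0, 1))
        assert out.size == 0

    def test_window_filters_events(self):
        ph = np.linspace(-np.pi, np.pi, 1000)
        out = phase_at_events(ph, 1000.0, [0.1, 0.5, 0.9],
                              window=(0.4, 0.6))
        assert out.size == 1


class TestCircularMean:
    def test_concentrated_angles(self):
        d, r = circular_mean(np.full(5, np.pi / 2))
        assert abs(d - np.pi / 2) < 1e-12 and abs(r - 1.0) < 1e-12

    def test_antipodal_pair_degenerate(self):
        with pytest.warns(UserWarning):
            d, r = circular_mean(np.array([0.0, np.pi]))
        assert r == 0.0

    def test_quarter_turn_pair(self):
        d, r = circular_mean(np.array([0.0, np.pi / 2]))
        assert abs(d - np.pi / 4) < 1e-12
        assert abs(r - np.sqrt(2) / 2) < 1e-12

    def test_rotation_equivariance(self, rng):
        ang = rng.uniform(-np.pi, np.pi, 50)
        d0, r0 = circular_mean(ang)
        delta = 1.1
        d1, r1 = circular_mean(ang + delta)
        assert abs(r1 - r0) < 1e-12
        assert abs(np.angle(np.exp(1j * (d1 - d0 - delta)))) < 1e-9


class TestPeriEventHistogram:
    def test_single_event_rate(self):
        centers, rate = peri_event_histogram([[0.01], []], (0.0, 1.0))
        assert np.isclose(rate[0], 10.0)  # 1 / (2 trials x 0.05 s)
        assert rate[1:].sum() == 0.0

    def test_no_events_all_zero(self):
        _, rate = peri_event_histogram([[], [], []], (-1.0, 3.0))
        assert np.all(rate == 0.0)

    def test_conservation_identity_exact(self, rng):
        trials = [rng.uniform(0, 2, rng.integers(0, 8)) for _ in range(7)]
        window = (0.0, 2.0)
        _, rate = peri_event_histogram(trials, window)
        total = sum(((ev >= 0) & (ev < 2.0)).sum() for ev in trials)
        assert np.isclose(rate.sum() * 0.05 * 7, total)

    def test_bin_wider_than_window_rejected(self):
        with pytest.raises(ValueError):
            peri_event_histogram([[0.0]], (0.0, 0.04), bin_width=0.05)


class TestCrossHistogram:
    def test_coincident_pair_all_in_lag_zero_bin(self):
        centers, pct = event_onset_cross_histogram([1.0], [1.0])
        k = np.argmax(pct)
        assert pct[k] == 100.0
        assert 0.0 <= centers[k] <= 0.05

    def test_percentages_sum_to_100_inside_window(self, rng):
        spindles = np.arange(5.0, 50.0, 5.0)
        ripples = spindles + rng.uniform(-0.9, 0.9, len(spindles))
        _, pct = event_onset_cross_histogram(ripples, spindles)
        assert np.isclose(pct.sum(), 100.0)

    def test_injected_lag_recovered(self):
        spindles = np.arange(5.0, 50.0, 5.0)
        ripples = spindles + 0.37
        centers, pct = event_onset_cross_histogram(ripples, spindles)
        assert abs(centers[np.argmax(pct)] - 0.37) <= 0.025

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            event_onset_cross_histogram([], [1.0])
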