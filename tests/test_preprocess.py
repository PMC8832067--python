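"""Episode extraction, window labeling (against brute force), DJD flag,
splits and standardization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from marscrash.preprocess import (Episode, EndCause, Standardizer, TEST, TRAIN,
                                  assign_folds, djd_flag, extract_episodes,
                                  make_all_windows, make_windows,
                                  split_episodes, window_length)

import helpers


def crash_episode(n_samples=150, dt=0.02):
    """Synthetic crash-terminated episode with t = dt .. n*dt."""
    t = dt * np.arange(1, n_samples + 1)
    theta = np.linspace(0.0, 60.0, n_samples)
    omega = np.gradient(theta, dt)
    joystick = np.zeros(n_samples)
    return Episode(trial_id=0, start=0, stop=n_samples,
                   end_cause=EndCause.CRASH, t=t, theta=theta, omega=omega,
                   joystick=joystick, episode_id=0)


class TestWindowing:
    def test_spec_worked_example(self):
        # 3.00 s crash episode, window 1000 ms, advance 800 ms, stride 1:
        # 101 windows; the 41 ending at t >= 2.20 s are labeled 1
        ep = crash_episode(150)
        w = make_windows(ep, 1000.0, 800.0, 1)
        assert len(w) == 101
        assert int(w.y.sum()) == 41
        assert np.all(w.end_time[w.y == 1] >= 2.20 - 1e-9)
        assert np.all(w.end_time[w.y == 0] < 2.20)
        assert w.X.shape == (101, 50, 4)

    def test_window_length(self):
        assert window_length(1000.0, 0.02) == 50
        assert window_length(300.0, 0.02) == 15

    def test_advance_zero_all_negative(self):
        w = make_windows(crash_episode(150), 1000.0, 0.0, 1)
        assert int(w.y.sum()) == 0

    def test_label_count_monotone_in_advance(self):
        ep = crash_episode(200)
        n300 = int(make_windows(ep, 1000.0, 300.0, 1).y.sum())
        n1000 = int(make_windows(ep, 1000.0, 1000.0, 1).y.sum())
        assert n300 <= n1000
        # closed at the window end: adv_steps + 1 window ends qualify
        assert n300 == 16 and n1000 == 51

    def test_short_episode_yields_none(self):
        assert make_windows(crash_episode(30), 1000.0, 800.0, 1) is None

    @given(n=st.integers(50, 400), stride=st.integers(1, 7))
    def test_window_count_formula(self, n, stride):
        w = make_windows(crash_episode(n), 1000.0, 800.0, stride)
        assert len(w) == (n - 50) // stride + 1

    def test_labels_match_bruteforce(self, small_episodes, small_windows):
        assert helpers.window_label_mismatches(small_episodes,
                                               small_windows) == []

    def test_djd_channel_consistency(self, small_windows):
        X = small_windows.X
        expect = ((np.sign(X[:, :, 0]) != 0)
                  & (np.sign(X[:, :, 0]) == np.sign(X[:, :, 1]))
                  & (np.sign(X[:, :, 0]) == np.sign(X[:, :, 2])))
        assert np.array_equal(X[:, :, 3].astype(bool), expect)

    def test_windows_never_overlap_resets(self, small_trials, small_windows):
        L = 50
        for i in range(0, len(small_windows), 37):
            trial = small_trials[int(small_windows.trial_id[i])]
            e = int(small_windows.end_index[i])
            assert np.all(trial.control_enabled[e - L + 1:e + 1])


class TestEpisodes:
    def test_balance_time_conservation(self, small_trials, small_episodes):
        for tid, trial in enumerate(small_trials):
            eps = [e for e in small_episodes if e.trial_id == tid]
            total = sum(e.duration for e in eps)
            assert total == pytest.approx(trial.params.trial_balance_seconds,
                                          abs=trial.params.dt)

    def test_crash_episode_count_and_boundary(self, small_trials,
                                              small_episodes):
        n_crashes = sum(len(t.crash_times) for t in small_trials)
        crash_eps = [e for e in small_episodes
                     if e.end_cause is EndCause.CRASH]
        assert len(crash_eps) == n_crashes
        for e in crash_eps:
            assert abs(e.theta[-1]) == 60.0
            assert e.crash_time == pytest.approx(e.t[-1])
            assert e.time_to_crash()[-1] == 0.0

    def test_trial_end_episode(self, small_episodes):
        te = [e for e in small_episodes if e.end_cause is EndCause.TRIAL_END]
        assert te  # each trial contributes its final segment
        assert np.all(np.isinf(te[0].time_to_crash()))

    def test_unique_ids(self, small_episodes):
        ids = [e.episode_id for e in small_episodes]
        assert ids == list(range(len(ids)))


class TestDJD:
    def test_27_case_enumeration(self):
        assert helpers.djd_enumeration_failures() == []

    def test_vectorized(self):
        out = djd_flag(np.array([5.0, 5.0, 0.0]), np.array([10.0, 10.0, 1.0]),
                       np.array([0.3, -0.3, 1.0]))
        assert out.tolist() == [1, 0, 0]


class TestSplits:
    def test_exact_counts(self):
        assign = split_episodes(list(range(10)), 0.9, seed=0)
        vals = list(assign.values())
        assert vals.count(TRAIN) == 9 and vals.count(TEST) == 1

    def test_deterministic_and_partition(self):
        a = split_episodes(list(range(100)), 0.8, seed=5)
        b = split_episodes(list(range(100)), 0.8, seed=5)
        assert a == b
        assert set(a) == set(range(100))

    def test_validation(self):
        with pytest.raises(ValueError):
            split_episodes([], 0.9)
        with pytest.raises(ValueError):
            split_episodes([1, 2], 1.5)

    def test_fold_balance(self):
        folds = assign_folds(list(range(25)), k=10, seed=0)
        sizes = np.bincount(list(folds.values()))
        assert sizes.max() - sizes.min() <= 1
        assert len(sizes) == 10

    def test_fold_validation(self):
        with pytest.raises(ValueError):
            assign_folds(list(range(5)), k=10)
        with pytest.raises(ValueError):
            assign_folds(list(range(5)), k=1)

    def test_leakage_audit(self, small_windows):
        ids = sorted({int(e) for e in small_windows.episode_id})
        assign = split_episodes(ids, 0.9, seed=0)
        assert helpers.leakage_overlap(small_windows, assign) == set()


class TestStandardizer:
    def test_zscoring(self, small_windows):
        std = Standardizer.fit(small_windows)
        out = std.transform(small_windows)
        flat = out.X[:, :, :3].reshape(-1, 3)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-9)
        # DJD channel untouched; raw max |theta| preserved for analyses
        assert np.array_equal(out.X[:, :, 3], small_windows.X[:, :, 3])
        assert np.array_equal(out.max_abs_theta, small_windows.max_abs_theta)
        # input unmodified
        assert not np.allclose(out.X[:, :, 0], small_windows.X[:, :, 0])
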