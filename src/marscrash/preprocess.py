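"""Episode extraction, sliding-window labeling, and leakage-safe splits.

An *episode* is a maximal contiguous run of human-controlled samples —
no crash strictly inside, no reset samples.  Sliding windows of device
readings (angular position, velocity, joystick deflection, plus a
destabilizing-joystick-deflection flag per step) are cut from episodes
and labeled 1 when a crash occurs within the *time-in-advance* interval
after the window's end.  Splits and cross-validation folds are assigned
at the episode level so that no window of an episode can appear on both
sides of a train/evaluate boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .dynamics import TrialRecord


class EndCause(Enum):
    CRASH = "CRASH"
    TRIAL_END = "TRIAL_END"


@dataclass
class Episode:
    """Maximal crash-free, human-controlled segment of one trial.

    ``start``/``stop`` is a 0-based half-open sample range into the
    parent trial; the channel arrays are views over that range.  For a
    crash-terminated episode the crash sample (|theta| at the boundary)
    is the last sample.
    """

    trial_id: int
    start: int
    stop: int
    end_cause: EndCause
    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    joystick: np.ndarray
    episode_id: int = -1

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def duration(self) -> float:
        """Episode duration in seconds (n_samples * dt)."""
        if self.n_samples < 2:
            return 0.0 if self.n_samples == 0 else float("nan")
        return self.n_samples * float(self.t[1] - self.t[0])

    @property
    def crash_time(self) -> Optional[float]:
        return float(self.t[-1]) if self.end_cause is EndCause.CRASH else None

    def time_to_crash(self) -> np.ndarray:
        """Seconds until the crash, per sample; inf for TRIAL_END episodes."""
        if self.end_cause is EndCause.CRASH:
            return self.t[-1] - self.t
        return np.full(self.n_samples, np.inf)


def extract_episodes(trial: TrialRecord, trial_id: int = 0) -> List[Episode]:
    """Split a trial into its maximal control-enabled runs."""
    trial.validate()
    ctrl = np.asarray(trial.control_enabled, dtype=bool)
    n = len(ctrl)
    if n == 0:
        return []
    # boundaries of True-runs
    padded = np.concatenate(([False], ctrl, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    crash_set = np.asarray(trial.crash_times)
    dt = trial.params.dt
    episodes = []
    for s, e in zip(starts, stops):
        t_last = trial.t[e - 1]
        is_crash = bool(len(crash_set)
                        and np.min(np.abs(crash_set - t_last)) < dt / 2)
        episodes.append(Episode(
            trial_id=trial_id, start=int(s), stop=int(e),
            end_cause=EndCause.CRASH if is_crash else EndCause.TRIAL_END,
            t=trial.t[s:e], theta=trial.theta[s:e],
            omega=trial.omega[s:e], joystick=trial.joystick[s:e],
        ))
    return episodes


def extract_all_episodes(trials: Sequence[TrialRecord]) -> List[Episode]:
    """Episodes of a trial collection, with globally unique episode ids."""
    episodes: List[Episode] = []
    for tid, trial in enumerate(trials):
        episodes.extend(extract_episodes(trial, trial_id=tid))
    for i, ep in enumerate(episodes):
        ep.episode_id = i
    return episodes


def djd_flag(theta, omega, joystick):
    """Destabilizing-joystick-deflection flag (vectorized).

    1 iff position, velocity and joystick deflection all share the same
    nonzero sign — a command accelerating the device toward the crash
    boundary.  A zero in any channel carries no sign and breaks the DJD.
    """
    st, so, sj = np.sign(theta), np.sign(omega), np.sign(joystick)
    out = (st != 0) & (st == so) & (st == sj)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return int(out)
    return out.astype(np.int8)


@dataclass
class WindowSet:
    """Vectorized container of labeled sliding-window samples.

    ``X`` has shape (N, L, 4) with channels (theta deg, omega deg/s,
    joystick, djd flag); ``y`` is 0/1 (crash within the time-in-advance
    interval after the window end); ``end_time`` is the time of each
    window's last sample; ``end_index`` that sample's index within the
    parent trial.
    """

    X: np.ndarray
    y: np.ndarray
    episode_id: np.ndarray
    trial_id: np.ndarray
    end_time: np.ndarray
    end_index: np.ndarray
    window_ms: float
    advance_ms: float
    stride_steps: int
    # raw-degree per-window max |theta|, preserved across standardization
    max_theta_raw: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.y)

    def __getitem__(self, i: int) -> "WindowSample":
        return WindowSample(self.X[i], int(self.y[i]), int(self.episode_id[i]),
                            float(self.end_time[i]), self.advance_ms)

    @property
    def max_abs_theta(self) -> np.ndarray:
        """Largest |position| (deg) within each window (failure stratifier)."""
        if self.max_theta_raw is not None:
            return self.max_theta_raw
        return np.abs(self.X[:, :, 0]).max(axis=1)

    def subset(self, mask) -> "WindowSet":
        mt = None if self.max_theta_raw is None else self.max_theta_raw[mask]
        return WindowSet(self.X[mask], self.y[mask], self.episode_id[mask],
                         self.trial_id[mask], self.end_time[mask],
                         self.end_index[mask], self.window_ms,
                         self.advance_ms, self.stride_steps, mt)


@dataclass
class WindowSample:
    features: np.ndarray  # (L, 4)
    label: int
    episode_id: int
    end_time: float
    advance_ms: float


def window_length(window_ms: float, dt: float) -> int:
    return int(round(window_ms / (dt * 1000.0)))


def make_windows(episode: Episode, window_ms: float = 1000.0,
                 advance_ms: float = 800.0, stride_steps: int = 1,
                 dt: Optional[float] = None) -> Optional[WindowSet]:
    """Cut labeled sliding windows out of one episode.

    A window of L = round(window_ms/dt) samples advances by
    ``stride_steps``.  Label 1 iff the episode ends in a crash at time c
    with end <= c <= end + advance (closed at the window end: a crash
    coinciding with the final sample is an imminent crash); with
    advance_ms = 0 every label is 0.  Episodes shorter than one window
    yield None.
    """
    if dt is None:
        if episode.n_samples < 2:
            return None
        dt = float(episode.t[1] - episode.t[0])
    L = window_length(window_ms, dt)
    n = episode.n_samples
    if L < 1 or n < L:
        return None
    adv_steps = int(round(advance_ms / (dt * 1000.0)))

    ends = np.arange(L - 1, n, stride_steps)  # index of last sample in window
    m = len(ends)
    feats = np.empty((m, L, 4))
    djd = djd_flag(episode.theta, episode.omega, episode.joystick)
    for j, e in enumerate(ends):
        s = e - L + 1
        feats[j, :, 0] = episode.theta[s:e + 1]
        feats[j, :, 1] = episode.omega[s:e + 1]
        feats[j, :, 2] = episode.joystick[s:e + 1]
        feats[j, :, 3] = djd[s:e + 1]

    if episode.end_cause is EndCause.CRASH and adv_steps > 0:
        y = ((n - 1) - ends <= adv_steps).astype(np.int8)
    else:
        y = np.zeros(m, dtype=np.int8)

    return WindowSet(
        X=feats, y=y,
        episode_id=np.full(m, episode.episode_id, dtype=np.int64),
        trial_id=np.full(m, episode.trial_id, dtype=np.int64),
        end_time=episode.t[ends].astype(float),
        end_index=(episode.start + ends).astype(np.int64),
        window_ms=window_ms, advance_ms=advance_ms, stride_steps=stride_steps,
    )


def make_all_windows(episodes: Sequence[Episode], window_ms: float = 1000.0,
                     advance_ms: float = 800.0,
                     stride_steps: int = 1) -> WindowSet:
    """Concatenate the window sets of many episodes (short ones skipped)."""
    parts = [w for w in (make_windows(ep, window_ms, advance_ms, stride_steps)
                         for ep in episodes) if w is not None and len(w)]
    if not parts:
        raise ValueError("no episode long enough for the requested window")
    return WindowSet(
        X=np.concatenate([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        episode_id=np.concatenate([p.episode_id for p in parts]),
        trial_id=np.concatenate([p.trial_id for p in parts]),
        end_time=np.concatenate([p.end_time for p in parts]),
        end_index=np.concatenate([p.end_index for p in parts]),
        window_ms=window_ms, advance_ms=advance_ms, stride_steps=stride_steps,
    )


TRAIN, TEST = "TRAIN", "TEST"


def split_episodes(episode_ids: Sequence[int], train_fraction: float = 0.9,
                   seed: int = 0) -> Dict[int, str]:
    """Uniform episode-level train/test split.

    Exactly floor(train_fraction * N) episodes land in TRAIN; all
    windows of an episode inherit its side, preventing leakage.
    """
    ids = [int(getattr(e, "episode_id", e)) for e in episode_ids]
    n = len(ids)
    if n == 0:
        raise ValueError("no episodes to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    assign = {}
    for rank, j in enumerate(perm):
        assign[ids[j]] = TRAIN if rank < n_train else TEST
    return assign


def assign_folds(episode_ids: Sequence[int], k: int = 10,
                 seed: int = 0) -> Dict[int, int]:
    """Episode-level partition into k folds with sizes differing by <= 1."""
    ids = [int(getattr(e, "episode_id", e)) for e in episode_ids]
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} episodes")
    perm = np.random.default_rng(seed).permutation(n)
    return {ids[j]: rank % k for rank, j in enumerate(perm)}


@dataclass
class Standardizer:
    """Per-channel z-scoring with statistics from the training split only.

    The three continuous channels (position, velocity, joystick) are
    z-scored; the binary DJD flag is left untouched.
    """

    mean: np.ndarray
    sd: np.ndarray

    N_CONTINUOUS = 3

    @classmethod
    def fit(cls, windows: WindowSet) -> "Standardizer":
        c = cls.N_CONTINUOUS
        flat = windows.X[:, :, :c].reshape(-1, c)
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mean=mean, sd=sd)

    def transform(self, windows: WindowSet) -> WindowSet:
        c = self.N_CONTINUOUS
        X = windows.X.copy()
        X[:, :, :c] = (X[:, :, :c] - self.mean) / self.sd
        return WindowSet(X, windows.y, windows.episode_id, windows.trial_id,
                         windows.end_time, windows.end_index,
                         windows.window_ms, windows.advance_ms,
                         windows.stride_steps,
                         max_theta_raw=windows.max_abs_theta.copy())
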