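"""Brute-force oracles and property checks shared by the unit tests and
the acceptance suite."""

import itertools

import numpy as np

from marscrash.dynamics import MarsState, SimParams, step
from marscrash.preprocess import EndCause, djd_flag


# --------------------------------------------------------------------- RK4
def free_pendulum_trajectory(theta0, omega0, dt, t_end, kp=600.0):
    """Unclamped free-pendulum state at t_end via the package's RK4 step."""
    params = SimParams(pendulum_constant=kp, dt=dt,
                       crash_boundary=90.0)  # boundary irrelevant here
    state = MarsState(theta=theta0, omega=omega0)
    for _ in range(int(round(t_end / dt))):
        state = step(state, 0.0, params, clamp=False)
    return state.theta, state.omega


def rk4_error_ratio(theta0=10.0, omega0=0.0, t_end=1.0):
    """Global-error ratio when halving dt (O(dt^4) => ~16x)."""
    ref, _ = free_pendulum_trajectory(theta0, omega0, 1e-4, t_end)
    e_coarse = abs(free_pendulum_trajectory(theta0, omega0, 0.02, t_end)[0] - ref)
    e_fine = abs(free_pendulum_trajectory(theta0, omega0, 0.01, t_end)[0] - ref)
    return e_coarse / e_fine


def fine_euler_step(theta0, omega0, dt_macro=0.02, dt_micro=1e-5, kp=600.0,
                    acc_limit=180.0):
    """Explicit-Euler oracle for one macro step of the clamped pendulum."""
    theta, omega = float(theta0), float(omega0)
    for _ in range(int(round(dt_macro / dt_micro))):
        acc = np.clip(kp * np.sin(np.deg2rad(theta)), -acc_limit, acc_limit)
        theta += dt_micro * omega
        omega += dt_micro * acc
    return theta, omega


# --------------------------------------------------------------------- DJD
def djd_enumeration_failures():
    """All (sign, sign, sign) cases vs the brute-force rule; [] if correct."""
    bad = []
    for a, b, c in itertools.product((-1.0, 0.0, 1.0), repeat=3):
        expect = int(a != 0 and a == b == c)
        if djd_flag(a * 5, b * 10, c * 0.3) != expect:
            bad.append((a, b, c))
    return bad


# ----------------------------------------------------------------- labeling
def window_label_mismatches(episodes, windows):
    """Compare every window label against a brute-force crash-time scan."""
    by_id = {ep.episode_id: ep for ep in episodes}
    dt = None
    mismatches = []
    for i in range(len(windows)):
        ep = by_id[int(windows.episode_id[i])]
        if dt is None:
            dt = float(ep.t[1] - ep.t[0])
        end = float(windows.end_time[i])
        crash = ep.crash_time
        expect = int(
            ep.end_cause is EndCause.CRASH
            and windows.advance_ms > 0
            and end - dt / 2 <= crash <= end + windows.advance_ms / 1000.0 + dt / 2)
        if int(windows.y[i]) != expect:
            mismatches.append(i)
    return mismatches


def leakage_overlap(windows, assignment):
    """Episode ids whose windows land on both sides of a split/fold map."""
    sides = {}
    bad = set()
    for eid in windows.episode_id:
        side = assignment[int(eid)]
        if sides.setdefault(int(eid), side) != side:
            bad.add(int(eid))
    # windows of one episode always share the episode's single assignment,
    # so the real audit is side-disjointness of the episode sets:
    groups = {}
    for eid, side in assignment.items():
        groups.setdefault(side, set()).add(eid)
    for s1, g1 in groups.items():
        for s2, g2 in groups.items():
            if s1 != s2 and g1 & g2:
                bad |= g1 & g2
    return bad


# ------------------------------------------------------------------ metrics
def auc_bruteforce(scores, labels):
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def precision_sweep_bruteforce(scores, labels, target):
    """Largest distinct-score threshold reaching the target recall."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    best = None
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        if tp / n_pos >= target - 1e-12:
            best = (tp / max(int(pred.sum()), 1), thr)
            break
    return best


def max_precision_at_recall(scores, labels, target):
    """Max precision over all qualifying cuts (provably monotone in target)."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    best = -1.0
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        if tp / n_pos >= target - 1e-12:
            best = max(best, tp / int(pred.sum()))
    return best


# ------------------------------------------------- recoverable-region search
def random_policy_saves_state(theta0, omega0, params, rng, n_policies=8,
                              horizon_s=10.0, hold_steps=5):
    """True if any random piecewise-constant policy avoids a crash."""
    n_steps = int(round(horizon_s / params.dt))
    for _ in range(n_policies):
        state = MarsState(theta=float(theta0), omega=float(omega0))
        u = 0.0
        crashed = False
        for k in range(n_steps):
            if k % hold_steps == 0:
                u = float(rng.uniform(-1.0, 1.0))
            state = step(state, u, params)
            if abs(state.theta) >= params.crash_boundary:
                crashed = True
                break
        if not crashed:
            return True
    return False
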