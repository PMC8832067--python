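"""Post-hoc failure analyses: where predictions fail and which crashes
could still have been saved.

Four analyses over the prediction records of a fitted model:

* misclassification rates stratified by the farthest |position| reached
  inside the data window (crashes from near the balance point are the
  hard false negatives);
* the share of each prediction type whose time-in-advance interval
  contains a destabilizing joystick deflection (DJD) — the mechanism
  behind near-0-degree false negatives;
* (position, velocity) density maps of the advance-interval states per
  prediction type;
* a recoverable region computed by bounded-control backward
  reachability, and the fraction of crashes still savable as warning
  time elapses.

The recoverable region is the viability kernel of |theta| < boundary
under |u| <= 1: a state is recoverable iff full braking (oppose the
velocity until stopped, then oppose position) keeps the device inside
the boundaries.  Because the control authority (joystick_gain/dt) of
the default configuration exceeds the clamped pendulum acceleration,
every stopped interior state can be driven home, which makes this
extremal policy optimal; randomized-policy search cannot beat it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import DEG, SimParams, TrialRecord, pendulum_acceleration
from .evaluation import prediction_types
from .predictors import PredictionRecord
from .preprocess import djd_flag

PRED_TYPES = ("TP", "FP", "FN", "TN")


def misclassification_by_position(predictions: Sequence[PredictionRecord],
                                  threshold: float,
                                  bin_edges: Optional[Sequence[float]] = None,
                                  crash_boundary: float = 60.0) -> dict:
    """Error rates per bin of the window's max |position|.

    Returns per-bin false-negative rate among crash samples and
    false-positive rate among non-crash samples (NaN where a bin holds
    no samples of that class), plus the per-bin counts.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.0, crash_boundary, 7)  # 6 bins of 10 deg
    edges = np.asarray(bin_edges, dtype=float)
    maxima = np.array([p.max_abs_theta for p in predictions])
    y = np.array([p.label for p in predictions])
    s = np.array([p.score for p in predictions])
    pred = s >= threshold
    which = np.clip(np.digitize(maxima, edges) - 1, 0, len(edges) - 2)

    nb = len(edges) - 1
    out = {"bin_edges": edges.tolist(), "fn_rate": [], "fp_rate": [],
           "n_crash": [], "n_noncrash": []}
    for b in range(nb):
        in_bin = which == b
        pos, neg = in_bin & (y == 1), in_bin & (y == 0)
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        out["n_crash"].append(n_pos)
        out["n_noncrash"].append(n_neg)
        out["fn_rate"].append(float(np.mean(~pred[pos])) if n_pos else float("nan"))
        out["fp_rate"].append(float(np.mean(pred[neg])) if n_neg else float("nan"))
    return out


def _advance_slice(record: PredictionRecord, trials: Sequence[TrialRecord],
                   adv_steps: int) -> slice:
    trial = trials[record.trial_id]
    start = record.end_index + 1
    return slice(start, min(start + adv_steps, len(trial.t)))


def djd_rate_by_prediction_type(predictions: Sequence[PredictionRecord],
                                trials: Sequence[TrialRecord],
                                advance_ms: float, threshold: float,
                                mode: str = "any") -> Dict[str, float]:
    """Share of windows whose advance interval contains a DJD, per type.

    ``mode="any"`` flags an interval containing >= 1 DJD step;
    ``mode="fraction"`` averages the per-step DJD flag instead.
    """
    if mode not in ("any", "fraction"):
        raise ValueError("mode must be 'any' or 'fraction'")
    types = prediction_types(predictions, threshold)
    dt = trials[0].params.dt
    adv_steps = int(round(advance_ms / (dt * 1000.0)))
    acc: Dict[str, List[float]] = {k: [] for k in PRED_TYPES}
    for rec, kind in zip(predictions, types):
        sl = _advance_slice(rec, trials, adv_steps)
        trial = trials[rec.trial_id]
        ctrl = trial.control_enabled[sl]
        flags = djd_flag(trial.theta[sl], trial.omega[sl],
                         trial.joystick[sl])
        flags = np.asarray(flags)[np.asarray(ctrl, dtype=bool)]
        if len(flags) == 0:
            val = 0.0
        elif mode == "any":
            val = float(flags.any())
        else:
            val = float(flags.mean())
        acc[str(kind)].append(val)
    return {k: (float(np.mean(v)) if v else float("nan"))
            for k, v in acc.items()}


def state_density_by_type(predictions: Sequence[PredictionRecord],
                          trials: Sequence[TrialRecord], advance_ms: float,
                          threshold: float,
                          theta_bins: int = 24, omega_bins: int = 24,
                          params: Optional[SimParams] = None) -> dict:
    """Normalized (theta, omega) histograms of advance-interval states."""
    if params is None:
        params = trials[0].params
    t_edges = np.linspace(-params.crash_boundary, params.crash_boundary,
                          theta_bins + 1)
    o_edges = np.linspace(-params.velocity_limit, params.velocity_limit,
                          omega_bins + 1)
    types = prediction_types(predictions, threshold)
    dt = params.dt
    adv_steps = int(round(advance_ms / (dt * 1000.0)))
    pools: Dict[str, List[np.ndarray]] = {k: [] for k in PRED_TYPES}
    for rec, kind in zip(predictions, types):
        sl = _advance_slice(rec, trials, adv_steps)
        trial = trials[rec.trial_id]
        ctrl = np.asarray(trial.control_enabled[sl], dtype=bool)
        pools[str(kind)].append(np.column_stack(
            [trial.theta[sl][ctrl], trial.omega[sl][ctrl]]))
    out = {"theta_edges": t_edges.tolist(), "omega_edges": o_edges.tolist(),
           "density": {}, "mean_abs_theta": {}, "mean_abs_omega": {}}
    for kind, chunks in pools.items():
        pts = (np.concatenate(chunks) if chunks
               else np.empty((0, 2)))
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                    bins=[t_edges, o_edges])
        total = hist.sum()
        out["density"][kind] = (hist / total if total > 0 else hist).tolist()
        out["mean_abs_theta"][kind] = (float(np.mean(np.abs(pts[:, 0])))
                                       if len(pts) else float("nan"))
        out["mean_abs_omega"][kind] = (float(np.mean(np.abs(pts[:, 1])))
                                       if len(pts) else float("nan"))
    return out


# ---------------------------------------------------------------------------
# recoverable region (viability kernel) and savability
# ---------------------------------------------------------------------------

def _extremal_rollout(theta0, omega0, params: SimParams,
                      horizon_s: float) -> np.ndarray:
    """Vectorized braking-policy rollout; True where a crash ever occurs.

    Policy per step: full deflection opposing the velocity; oppose the
    position once (nearly) stopped.  Integration mirrors the simulator:
    joystick velocity increment, then RK4 on the clamped pendulum, with
    the device velocity clamp applied.
    """
    theta = np.array(theta0, dtype=float, ndmin=1).copy()
    omega = np.array(omega0, dtype=float, ndmin=1).copy()
    dt = params.dt
    vlim = params.velocity_limit
    b = params.crash_boundary
    crashed = np.abs(theta) >= b
    n_steps = int(round(horizon_s / dt))
    for _ in range(n_steps):
        u = np.where(omega != 0.0, -np.sign(omega), -np.sign(theta))
        omega = np.clip(omega + params.joystick_gain * u, -vlim, vlim)
        # RK4 on the free clamped pendulum (vectorized)
        k1t, k1o = omega, pendulum_acceleration(theta, params)
        th2 = theta + 0.5 * dt * k1t
        om2 = np.clip(omega + 0.5 * dt * k1o, -vlim, vlim)
        k2t, k2o = om2, pendulum_acceleration(th2, params)
        th3 = theta + 0.5 * dt * k2t
        om3 = np.clip(omega + 0.5 * dt * k2o, -vlim, vlim)
        k3t, k3o = om3, pendulum_acceleration(th3, params)
        th4 = theta + dt * k3t
        om4 = np.clip(omega + dt * k3o, -vlim, vlim)
        k4t, k4o = om4, pendulum_acceleration(th4, params)
        theta = theta + (dt / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
        omega = np.clip(omega + (dt / 6.0) * (k1o + 2 * k2o + 2 * k3o + k4o),
                        -vlim, vlim)
        crashed |= np.abs(theta) >= b
        if crashed.all():
            break
    return crashed


@dataclass
class RecoverableRegion:
    """Grid of (theta, omega) states from which a crash is still avoidable."""

    theta_centers: np.ndarray
    omega_centers: np.ndarray
    recoverable: np.ndarray        # (n_theta, n_omega) bool
    params: SimParams
    horizon_s: float

    def is_recoverable(self, theta, omega) -> np.ndarray:
        """Exact (non-gridded) membership by extremal-policy rollout."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        return ~_extremal_rollout(theta, omega, self.params, self.horizon_s)

    def lookup(self, theta: float, omega: float) -> bool:
        """Nearest-cell grid membership (for maps; outside grid = False)."""
        if abs(theta) >= self.params.crash_boundary:
            return False
        i = int(np.argmin(np.abs(self.theta_centers - theta)))
        j = int(np.argmin(np.abs(self.omega_centers - omega)))
        return bool(self.recoverable[i, j])


def compute_recoverable_region(params: SimParams, n_theta: int = 61,
                               n_omega: int = 61,
                               horizon_s: float = 10.0) -> RecoverableRegion:
    """Backward-reachability region under full bounded joystick authority.

    A grid cell is recoverable iff the extremal braking policy keeps
    |theta| below the crash boundary for the whole horizon.  Cells at or
    beyond the boundary are unrecoverable by definition.
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    th = np.linspace(-params.crash_boundary, params.crash_boundary, n_theta)
    om = np.linspace(-params.velocity_limit, params.velocity_limit, n_omega)
    TH, OM = np.meshgrid(th, om, indexing="ij")
    crashed = _extremal_rollout(TH.ravel(), OM.ravel(), params, horizon_s)
    rec = ~crashed.reshape(n_theta, n_omega)
    rec[np.abs(th) >= params.crash_boundary, :] = False
    return RecoverableRegion(theta_centers=th, omega_centers=om,
                             recoverable=rec, params=params,
                             horizon_s=horizon_s)


@dataclass
class SavabilityReport:
    """Fraction of crashes still savable as the warning time elapses."""

    offsets_ms: List[float]
    savable_fraction: List[float]
    n_crashes: int
    advance_ms: float

    def as_percent(self) -> List[float]:
        return [100.0 * f for f in self.savable_fraction]


def crash_states_before(trials: Sequence[TrialRecord],
                        lookback_s: float) -> np.ndarray:
    """(theta, omega) at ``lookback_s`` before each crash, nearest sample
    at or before the offset, clipped to the crash's episode start."""
    states = []
    for trial in trials:
        dt = trial.params.dt
        lag = int(round(lookback_s / dt))
        ctrl = np.asarray(trial.control_enabled, dtype=bool)
        for ct in trial.crash_times:
            ci = int(np.argmin(np.abs(trial.t - ct)))
            # first index of the contiguous control-enabled run ending at ci
            ep_start = ci
            while ep_start > 0 and ctrl[ep_start - 1]:
                ep_start -= 1
            i = max(ci - lag, ep_start)
            states.append((trial.theta[i], trial.omega[i]))
    return np.asarray(states, dtype=float).reshape(-1, 2)


def savable_fraction(trials: Sequence[TrialRecord], region: RecoverableRegion,
                     advance_ms: float = 800.0,
                     offsets_ms: Sequence[float] = (0, 200, 400, 600, 800),
                     ) -> SavabilityReport:
    """Savable share of crashes when action starts ``offset`` after the
    prediction window ends.

    At elapsed offset e the relevant state sits (advance - e) before the
    impact; e = advance means the impact state itself (at the boundary,
    never recoverable, so the final column is exactly 0).
    """
    adv_s = advance_ms / 1000.0
    offsets = list(offsets_ms)
    if any(o < 0 or o > advance_ms for o in offsets):
        raise ValueError("offsets must lie in [0, advance_ms]")
    n_crashes = sum(len(t.crash_times) for t in trials)
    fracs = []
    for off in offsets:
        lookback = adv_s - off / 1000.0
        states = crash_states_before(trials, lookback)
        if len(states) == 0:
            fracs.append(float("nan"))
            continue
        rec = region.is_recoverable(states[:, 0], states[:, 1])
        fracs.append(float(np.mean(rec)))
    return SavabilityReport(offsets_ms=offsets, savable_fraction=fracs,
                            n_crashes=n_crashes, advance_ms=advance_ms)
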