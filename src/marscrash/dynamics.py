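"""Inverted-pendulum dynamics of the MARS balancing device.

The device rotates a seated participant about a single axis and is
programmed as an unstable inverted pendulum,

    theta_ddot = kP * sin(theta),

with ``theta`` the angular deviation from the direction of balance in
degrees and ``kP`` the pendulum constant in deg/s^2 (default 600, a
small-angle natural frequency of ~0.52 Hz).  Angular velocity is limited
to +/-300 deg/s and pendulum acceleration to +/-180 deg/s^2 — device
limits, enforced continuously.  At every 20 ms time step a velocity
increment proportional to the joystick deflection is added before the
pendulum term is integrated by a classic Runge–Kutta (RK4) step.

Reaching +/-60 deg is a crash: the device resets to 0 deg at 5 deg/s
with the joystick disabled, then balancing resumes.  A trial accumulates
100 s of balancing time, resets excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Callable, List, Optional, Sequence

import numpy as np

DEG = math.pi / 180.0


class Phase(Enum):
    BALANCING = "BALANCING"
    RESETTING = "RESETTING"


@dataclass(frozen=True)
class SimParams:
    """Physical and task constants of the simulated device.

    Attributes
    ----------
    pendulum_constant:
        kP in deg/s^2; scales the destabilizing pendulum acceleration.
    crash_boundary:
        Crash angle in deg; reaching +/- this value ends an episode.
    velocity_limit:
        Device angular-velocity limit, deg/s.
    acceleration_limit:
        Device limit on the pendulum acceleration term, deg/s^2.
    dt:
        Integration and sampling interval, s.
    joystick_gain:
        Velocity increment in deg/s added per step at full deflection
        (u = 1).  Equivalent control authority: joystick_gain/dt deg/s^2.
    reset_rate:
        Speed of the automatic post-crash return to 0 deg, deg/s.
    trial_balance_seconds:
        Cumulative balancing time per trial, resets excluded, s.
    """

    pendulum_constant: float = 600.0
    crash_boundary: float = 60.0
    velocity_limit: float = 300.0
    acceleration_limit: float = 180.0
    dt: float = 0.02
    joystick_gain: float = 6.0
    reset_rate: float = 5.0
    trial_balance_seconds: float = 100.0

    def __post_init__(self) -> None:
        for name in ("pendulum_constant", "crash_boundary", "velocity_limit",
                     "acceleration_limit", "dt", "joystick_gain", "reset_rate",
                     "trial_balance_seconds"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"SimParams.{name} must be finite and > 0, got {v!r}")
        if self.crash_boundary > 90:
            raise ValueError("crash_boundary must be <= 90 deg")
        if self.dt > 0.1:
            raise ValueError("dt must be in (0, 0.1] s")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MarsState:
    """Instantaneous device state: angle (deg), rate (deg/s), time (s)."""

    theta: float
    omega: float
    t: float = 0.0
    phase: Phase = Phase.BALANCING


@dataclass
class CrashEvent:
    t: float
    theta: float  # clipped to +/-crash_boundary


@dataclass
class TrialRecord:
    """One balancing trial, uniformly sampled at ``params.dt``.

    ``control_enabled`` is False exactly during the automatic resets;
    each crash time coincides with a sample at |theta| = crash_boundary.
    """

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    joystick: np.ndarray
    control_enabled: np.ndarray
    crash_times: List[float]
    params: SimParams
    seed: Optional[int] = None

    @property
    def cumulative_balance_time(self) -> float:
        return float(np.count_nonzero(self.control_enabled) * self.params.dt)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = self.n_samples
        for name in ("theta", "omega", "joystick", "control_enabled"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, self.params.dt, rtol=0, atol=1e-9):
            raise ValueError("non-uniform timestep in trial record")
        if np.any(~np.isfinite(self.theta)) or np.any(~np.isfinite(self.omega)):
            raise ValueError("non-finite sample in trial record")


def natural_frequency(params: SimParams) -> float:
    """Small-angle linearized frequency of theta_ddot = kP sin(theta), in Hz.

    With theta in degrees and the sine argument converted to radians,
    linearization gives theta_ddot = kP*(pi/180)*theta, hence
    f = sqrt(kP*pi/180) / (2*pi).  kP = 600 deg/s^2 yields ~0.515 Hz.
    """
    kp = params.pendulum_constant
    if kp <= 0:
        raise ValueError("pendulum_constant must be positive")
    return math.sqrt(kp * DEG) / (2.0 * math.pi)


def pendulum_acceleration(theta, params: SimParams):
    """Clamped pendulum acceleration kP*sin(theta), deg/s^2 (vectorized)."""
    acc = params.pendulum_constant * np.sin(np.asarray(theta) * DEG)
    return np.clip(acc, -params.acceleration_limit, params.acceleration_limit)


def _rk4_step(theta, omega, params: SimParams, clamp: bool = True):
    """One RK4 step of the free pendulum (no joystick term).

    Vectorized over arrays of states.  The acceleration clamp acts inside
    the right-hand side; the velocity clamp is applied to every
    intermediate and final state (device limits hold continuously).
    """
    dt = params.dt
    vlim = params.velocity_limit

    if clamp:
        def acc(th):
            return pendulum_acceleration(th, params)

        def clv(om):
            return np.clip(om, -vlim, vlim)
    else:
        def acc(th):
            return params.pendulum_constant * np.sin(np.asarray(th) * DEG)

        def clv(om):
            return om

    k1_th, k1_om = omega, acc(theta)
    th2, om2 = theta + 0.5 * dt * k1_th, clv(omega + 0.5 * dt * k1_om)
    k2_th, k2_om = om2, acc(th2)
    th3, om3 = theta + 0.5 * dt * k2_th, clv(omega + 0.5 * dt * k2_om)
    k3_th, k3_om = om3, acc(th3)
    th4, om4 = theta + dt * k3_th, clv(omega + dt * k3_om)
    k4_th, k4_om = om4, acc(th4)

    theta_new = theta + (dt / 6.0) * (k1_th + 2 * k2_th + 2 * k3_th + k4_th)
    omega_new = omega + (dt / 6.0) * (k1_om + 2 * k2_om + 2 * k3_om + k4_om)
    return theta_new, clv(omega_new)


def step(state: MarsState, joystick: float, params: SimParams,
         clamp: bool = True) -> MarsState:
    """Advance one balancing step: joystick velocity increment, then RK4.

    The joystick adds ``joystick_gain * u`` deg/s to the angular velocity
    once per step (discrete coupling), after which the free pendulum is
    integrated over one ``dt``.
    """
    if state.phase is not Phase.BALANCING:
        raise ValueError("step() requires phase=BALANCING")
    if not (np.isfinite(state.theta) and np.isfinite(state.omega)
            and np.isfinite(joystick)):
        raise ValueError("non-finite state or joystick input")
    if not -1.0 <= joystick <= 1.0:
        raise ValueError(f"joystick deflection {joystick} outside [-1, 1]")

    omega = state.omega + params.joystick_gain * joystick
    if clamp:
        omega = float(np.clip(omega, -params.velocity_limit, params.velocity_limit))
    theta_new, omega_new = _rk4_step(state.theta, omega, params, clamp=clamp)
    return MarsState(theta=float(theta_new), omega=float(omega_new),
                     t=state.t + params.dt, phase=Phase.BALANCING)


def detect_crash(state: MarsState, params: SimParams) -> Optional[CrashEvent]:
    """Crash iff |theta| has reached the boundary; theta recorded clipped."""
    if state.phase is not Phase.BALANCING:
        raise ValueError("detect_crash() requires phase=BALANCING")
    b = params.crash_boundary
    if abs(state.theta) >= b:
        return CrashEvent(t=state.t, theta=math.copysign(b, state.theta))
    return None


class History:
    """Read-only view of the balancing samples of the current episode.

    Passed to pilot callables so control laws can use delayed or
    integrated percepts without touching simulator internals.
    """

    __slots__ = ("t", "theta", "omega", "joystick", "dt")

    def __init__(self, t, theta, omega, joystick, dt):
        self.t = t
        self.theta = theta
        self.omega = omega
        self.joystick = joystick
        self.dt = dt

    def __len__(self) -> int:
        return len(self.t)


Pilot = Callable[[History, np.random.Generator], float]


def simulate_trial(pilot: Pilot, params: SimParams, seed: int = 0,
                   theta0: float = 0.0, omega0: float = 0.0) -> TrialRecord:
    """Run one trial: balancing until 100 s accumulate, resets in between.

    ``pilot`` maps (episode history so far, rng) -> joystick deflection in
    [-1, 1]; out-of-range values are clipped.  If the pilot object has a
    ``reset()`` method it is called at every episode start (the device
    announces "begin" and the participant starts fresh from 0 deg).
    Identical seeds produce bit-identical records.
    """
    rng = np.random.default_rng(seed)
    dt = params.dt
    n_balance_steps = int(round(params.trial_balance_seconds / dt))

    ts: List[float] = []
    thetas: List[float] = []
    omegas: List[float] = []
    joys: List[float] = []
    ctrl: List[bool] = []
    crash_times: List[float] = []

    # episode-local buffers backing the History view
    ep_t: List[float] = []
    ep_th: List[float] = []
    ep_om: List[float] = []
    ep_u: List[float] = []

    def begin_episode(state: MarsState) -> None:
        ep_t.clear(); ep_th.clear(); ep_om.clear(); ep_u.clear()
        ep_t.append(state.t); ep_th.append(state.theta)
        ep_om.append(state.omega); ep_u.append(0.0)
        if hasattr(pilot, "reset"):
            pilot.reset()

    state = MarsState(theta=theta0, omega=omega0, t=0.0)
    begin_episode(state)
    steps_done = 0

    while steps_done < n_balance_steps:
        hist = History(np.asarray(ep_t), np.asarray(ep_th),
                       np.asarray(ep_om), np.asarray(ep_u), dt)
        u = float(pilot(hist, rng))
        if not np.isfinite(u):
            raise ValueError("pilot returned non-finite deflection")
        if u < -1.0 or u > 1.0:
            u = float(np.clip(u, -1.0, 1.0))

        state = step(state, u, params)
        steps_done += 1

        crash = detect_crash(state, params)
        if crash is not None:
            state.theta = crash.theta
            ts.append(state.t); thetas.append(state.theta)
            omegas.append(state.omega); joys.append(u); ctrl.append(True)
            crash_times.append(state.t)

            # automatic reset toward 0 deg at reset_rate, joystick disabled
            sgn = math.copysign(1.0, state.theta)
            n_reset = int(round(abs(state.theta) / (params.reset_rate * dt)))
            for k in range(1, n_reset + 1):
                th = state.theta - sgn * params.reset_rate * dt * k
                if sgn * th < 0:
                    th = 0.0
                ts.append(state.t + k * dt)
                thetas.append(th)
                omegas.append(-sgn * params.reset_rate if th != 0.0 else 0.0)
                joys.append(0.0)
                ctrl.append(False)
            state = MarsState(theta=0.0, omega=0.0,
                              t=state.t + n_reset * dt, phase=Phase.BALANCING)
            begin_episode(state)
        else:
            ts.append(state.t); thetas.append(state.theta)
            omegas.append(state.omega); joys.append(u); ctrl.append(True)
            ep_t.append(state.t); ep_th.append(state.theta)
            ep_om.append(state.omega); ep_u.append(u)

    rec = TrialRecord(
        t=np.asarray(ts), theta=np.asarray(thetas), omega=np.asarray(omegas),
        joystick=np.asarray(joys),
        control_enabled=np.asarray(ctrl, dtype=bool),
        crash_times=crash_times, params=params, seed=seed,
    )
    rec.validate()
    return rec
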