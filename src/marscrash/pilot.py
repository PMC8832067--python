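"""Synthetic disoriented-pilot controllers.

In the horizontal-roll spaceflight analog the participant cannot sense
absolute tilt (no gravity-dependent shear cues); only motion cues from
the semicircular canals and rapidly adapting somatosensory receptors
remain.  The controller here models that deficit with three ingredients:

* a *leaky* integration of perceived velocity into a position estimate —
  the leak erases absolute position sense and produces the positional
  drift characteristic of disoriented operators;
* a sensorimotor *delay* and additive noise on perceived velocity;
* intermittent proportional–derivative commands issued on a 1–2 Hz
  decision clock and held in between, with an occasional *sign error*
  (a command in the destabilizing direction), the generative stand-in
  for the destabilizing joystick deflections seen in disoriented data.

The model is a data-shaped stand-in for human participants, not a
vestibular-physiology model: it exists so that every downstream stage
(windowing, training, failure analysis) can run on realistic trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import numpy as np

from .dynamics import History, SimParams, simulate_trial


@dataclass(frozen=True)
class PilotParams:
    """Parameters of the synthetic pilot.

    position_leak : 1/s
        Decay rate of the internal position estimate toward 0; 0 keeps a
        perfect integral, larger values produce stronger drift.
    estimate_noise_sd : deg/s
        SD of Gaussian noise on the perceived angular velocity.
    reaction_delay : s
        Sensorimotor delay applied to the velocity percept.
    kp, kd
        Proportional (per deg) and derivative (per deg/s) gains mapping
        the estimated state to a joystick deflection.
    deflection_rate_hz : Hz
        Decision-clock rate; commands are recomputed at this rate and
        held in between, matching the 1–2 Hz full-deflection rhythm of
        recorded joystick activity.
    sign_error_prob
        Stationary probability that a command is issued while the pilot
        is *disoriented*.  Disorientation is persistent, not a per-command
        coin flip: the pilot enters a disoriented mode and stays there
        for ``disorientation_mean_s`` seconds on average, issuing
        sign-flipped (destabilizing) commands throughout, the way a
        wrong internal sense of position persists until re-anchored.
    disorientation_mean_s : s
        Mean duration of a disoriented bout.
    """

    position_leak: float = 0.2
    estimate_noise_sd: float = 8.0
    reaction_delay: float = 0.4
    kp: float = 0.2
    kd: float = 0.35
    deflection_rate_hz: float = 1.5
    sign_error_prob: float = 0.1
    disorientation_mean_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sign_error_prob <= 1.0:
            raise ValueError("sign_error_prob must be in [0, 1]")
        if self.reaction_delay < 0:
            raise ValueError("reaction_delay must be >= 0")
        if self.kp < 0 or self.kd < 0:
            raise ValueError("gains must be >= 0")
        if self.estimate_noise_sd < 0 or self.position_leak < 0:
            raise ValueError("noise and leak must be >= 0")
        if self.deflection_rate_hz <= 0:
            raise ValueError("deflection_rate_hz must be positive")


class PilotController:
    """Stateful controller implementing the PilotParams control law.

    Usable directly as the ``pilot`` callable of
    :func:`marscrash.dynamics.simulate_trial`; ``reset()`` is invoked by
    the simulator at every episode start (the participant restarts from
    the balance point with no carried-over position sense).
    """

    def __init__(self, params: PilotParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self._theta_est = 0.0
        self._held_u = 0.0
        self._next_decision = 0.0
        self._elapsed = 0.0
        self._disoriented = False

    def __call__(self, history: History, rng: np.random.Generator) -> float:
        p = self.params
        dt = history.dt
        n = len(history)

        # delayed, noisy velocity percept
        lag = int(round(p.reaction_delay / dt))
        idx = max(0, n - 1 - lag)
        omega_perceived = history.omega[idx]
        if p.estimate_noise_sd > 0:
            omega_perceived = omega_perceived + rng.normal(0.0, p.estimate_noise_sd)

        # leaky integration of perceived velocity -> position estimate
        self._theta_est += dt * (omega_perceived - p.position_leak * self._theta_est)

        if self._elapsed >= self._next_decision - 1e-12:
            # persistent disorientation: a two-state Markov mode updated
            # at decision instants, with stationary occupancy
            # sign_error_prob and mean bout length disorientation_mean_s
            occ = p.sign_error_prob
            interval = 1.0 / p.deflection_rate_hz
            p_exit = min(1.0, interval / max(p.disorientation_mean_s, interval))
            if occ >= 1.0:
                self._disoriented = True
            elif occ <= 0.0:
                self._disoriented = False
            else:
                p_enter = min(1.0, occ / (1.0 - occ) * p_exit)
                if self._disoriented:
                    if rng.random() < p_exit:
                        self._disoriented = False
                else:
                    if rng.random() < p_enter:
                        self._disoriented = True
            u = -(p.kp * self._theta_est + p.kd * omega_perceived)
            if self._disoriented:
                u = -u
            self._held_u = float(np.clip(u, -1.0, 1.0))
            self._next_decision += 1.0 / p.deflection_rate_hz
        self._elapsed += dt

        return self._held_u


def pilot_control(history: History, params: PilotParams,
                  rng: np.random.Generator) -> float:
    """Pure-function form: replay ``history`` through a fresh controller.

    Returns the deflection the control law emits at the latest sample.
    O(n) per call; intended for contract tests, not the simulation loop
    (use :class:`PilotController` there).
    """
    if len(history) == 0:
        raise ValueError("history must be nonempty")
    ctl = PilotController(params)
    dt = history.dt
    u = 0.0
    for k in range(len(history)):
        sub = History(history.t[:k + 1], history.theta[:k + 1],
                      history.omega[:k + 1], history.joystick[:k + 1], dt)
        u = ctl(sub, rng)
    return u


def make_cohort(n_pilots: int, difficulty_spread: float = 1.0,
                seed: int = 0) -> List[PilotParams]:
    """Reproducible cohort spanning rarely- to frequently-crashing pilots.

    Difficulty d in [0, 1] is spread evenly across the cohort (scaled by
    ``difficulty_spread``) and mapped to parameters: higher d means more
    drift, noise, delay, sign errors and a slower decision clock.  Small
    per-pilot jitter keeps parameter sets distinct.
    """
    if n_pilots < 1:
        raise ValueError("n_pilots must be >= 1")
    rng = np.random.default_rng(seed)
    if n_pilots == 1:
        base = np.array([0.5])
    else:
        base = np.linspace(0.0, 1.0, n_pilots)
    cohort = []
    for i, d0 in enumerate(base):
        d = float(np.clip(d0 * difficulty_spread, 0.0, 1.0))
        jit = rng.uniform(0.95, 1.05, size=6)
        cohort.append(PilotParams(
            position_leak=(0.02 + 0.18 * d) * jit[0],
            estimate_noise_sd=(1.0 + 5.0 * d) * jit[1],
            reaction_delay=float(np.clip((0.08 + 0.02 * d) * jit[2], 0.0, 0.6)),
            kp=0.20 * jit[3],
            kd=0.35 * jit[4],
            deflection_rate_hz=float(np.clip((5.0 - 1.0 * d) * jit[5], 1.0, 6.0)),
            sign_error_prob=float(np.clip((0.02 + 0.10 * d) * jit[5], 0.0, 1.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return cohort


def simulate_cohort(cohort: List[PilotParams], params: SimParams,
                    trials_per_pilot: int, seed: int = 0,
                    theta0: float = 0.5):
    """Simulate ``trials_per_pilot`` trials for each pilot in the cohort.

    Returns a flat list of TrialRecord; trial seeds derive from ``seed``
    and the pilot's own seed so runs are reproducible end to end.
    ``theta0`` gives each trial a small initial offset so even noiseless
    pilots face a nontrivial task.
    """
    trials = []
    for i, pp in enumerate(cohort):
        ctl = PilotController(pp)
        for j in range(trials_per_pilot):
            trial_seed = (seed * 1_000_003 + pp.seed + 7919 * j) % (2**31 - 1)
            trials.append(simulate_trial(ctl, params, seed=trial_seed,
                                         theta0=theta0))
    return trials
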