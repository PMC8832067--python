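"""Synthetic-pilot contracts: stabilization, disorientation statistics,
monotone difficulty effects, cohort reproducibility."""

import numpy as np
import pytest

from marscrash.dynamics import History, SimParams, simulate_trial
from marscrash.pilot import (PilotController, PilotParams, make_cohort,
                             pilot_control, simulate_cohort)
from marscrash.preprocess import djd_flag


def stable_params(**overrides):
    base = dict(position_leak=0.0, estimate_noise_sd=0.0, reaction_delay=0.0,
                kp=0.3, kd=0.5, deflection_rate_hz=10.0, sign_error_prob=0.0)
    base.update(overrides)
    return PilotParams(**base)


def crash_count(params, sim, seed=0, theta0=1.0):
    return len(simulate_trial(PilotController(params), sim, seed=seed,
                              theta0=theta0).crash_times)


class TestControlLaw:
    def test_noiseless_pd_never_crashes(self, sim):
        assert crash_count(stable_params(), sim) == 0

    def test_forced_sign_inversion_is_destabilizing(self, sim):
        # deterministic: kd-only controller fed a positive-velocity percept
        # must push WITH the motion when sign_error_prob = 1
        ctl = PilotController(stable_params(kp=0.0, kd=1.0,
                                            sign_error_prob=1.0))
        rng = np.random.default_rng(0)
        h = History(np.array([0.0]), np.array([5.0]), np.array([20.0]),
                    np.array([0.0]), sim.dt)
        us = [ctl(h, rng) for _ in range(50)]
        assert all(u > 0 for u in us)

    def test_forced_inversion_crashes_often(self, sim):
        few = crash_count(stable_params(estimate_noise_sd=2.0), sim)
        many = crash_count(stable_params(estimate_noise_sd=2.0,
                                         sign_error_prob=1.0), sim)
        assert many > 10 * max(few, 1)

    def test_commands_bounded(self, small_trials):
        for t in small_trials:
            assert np.all(np.abs(t.joystick) <= 1.0)

    def test_determinism(self, short_sim):
        p = PilotParams(seed=3)
        a = simulate_trial(PilotController(p), short_sim, seed=5, theta0=0.5)
        b = simulate_trial(PilotController(p), short_sim, seed=5, theta0=0.5)
        assert np.array_equal(a.joystick, b.joystick)
        assert a.crash_times == b.crash_times

    def test_pure_function_form(self, sim):
        rng = np.random.default_rng(0)
        h = History(np.arange(5) * sim.dt, np.linspace(0.1, 0.5, 5),
                    np.linspace(1.0, 5.0, 5), np.zeros(5), sim.dt)
        u = pilot_control(h, PilotParams(), rng)
        assert -1.0 <= u <= 1.0
        with pytest.raises(ValueError):
            pilot_control(History(np.array([]), np.array([]), np.array([]),
                                  np.array([]), sim.dt), PilotParams(), rng)


class TestDisorientationBouts:
    def test_occupancy_and_bout_length(self, sim):
        # kd-only pilot on a constant-velocity percept: u > 0 exactly while
        # disoriented, so occupancy and bout statistics are observable
        p = stable_params(kp=0.0, kd=1.0, deflection_rate_hz=5.0,
                          sign_error_prob=0.3, disorientation_mean_s=1.5)
        ctl = PilotController(p)
        rng = np.random.default_rng(12345)
        h = History(np.array([0.0]), np.array([0.0]), np.array([10.0]),
                    np.array([0.0]), sim.dt)
        us = np.array([ctl(h, rng) for _ in range(100_000)])  # 2000 s
        dis = us > 0
        occupancy = float(dis.mean())
        assert abs(occupancy - 0.3) < 0.05
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], dis.astype(int), [0]))))
        bouts = (edges[1::2] - edges[::2]) * sim.dt
        assert abs(bouts.mean() - 1.5) < 0.4

    def test_leak_decays_position_estimate(self, sim):
        # after motion stops, a leaky pilot's position command fades while
        # the leak-free pilot's persists (loss of absolute position sense)
        def command_after_rest(leak):
            ctl = PilotController(stable_params(position_leak=leak, kp=1.0,
                                                kd=0.0, deflection_rate_hz=50.0))
            rng = np.random.default_rng(0)
            moving = History(np.array([0.0]), np.array([0.0]),
                             np.array([20.0]), np.array([0.0]), sim.dt)
            still = History(np.array([0.0]), np.array([0.0]),
                            np.array([0.0]), np.array([0.0]), sim.dt)
            for _ in range(100):
                ctl(moving, rng)
            u = 0.0
            for _ in range(500):  # 10 s at rest
                u = ctl(still, rng)
            return abs(u)

        assert command_after_rest(0.0) > 0.3
        assert command_after_rest(1.0) < 0.01


class TestDifficultyMonotonicity:
    def test_crashes_increase_with_sign_error(self, sim):
        def total(se):
            p = PilotParams(position_leak=0.1, estimate_noise_sd=4.0,
                            reaction_delay=0.1, kp=0.2, kd=0.35,
                            deflection_rate_hz=4.0, sign_error_prob=se)
            return sum(crash_count(p, sim, seed=s, theta0=0.5)
                       for s in (0, 1))

        counts = [total(se) for se in (0.02, 0.15, 0.4)]
        assert counts[0] < counts[1] < counts[2]

    def test_crashes_increase_with_noise(self, sim):
        def total(nz):
            p = PilotParams(position_leak=0.1, estimate_noise_sd=nz,
                            reaction_delay=0.1, kp=0.2, kd=0.35,
                            deflection_rate_hz=4.0, sign_error_prob=0.05)
            return sum(crash_count(p, sim, seed=s, theta0=0.5)
                       for s in (0, 1, 2))

        counts = [total(nz) for nz in (0.5, 4.0, 10.0)]
        assert counts[0] < counts[1] < counts[2]

    def test_crashes_increase_with_leak(self, sim):
        counts = [crash_count(stable_params(position_leak=leak,
                                            estimate_noise_sd=0.5),
                              sim, seed=7)
                  for leak in (0.0, 0.3, 0.6)]
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]

    def test_djd_fraction_increases_with_sign_error(self, sim):
        def djd_frac(se):
            p = PilotParams(position_leak=0.1, estimate_noise_sd=4.0,
                            reaction_delay=0.1, kp=0.2, kd=0.35,
                            deflection_rate_hz=4.0, sign_error_prob=se)
            t = simulate_trial(PilotController(p), sim, seed=0, theta0=0.5)
            m = t.control_enabled
            return float(np.mean(djd_flag(t.theta[m], t.omega[m],
                                          t.joystick[m])))

        assert djd_frac(0.4) > djd_frac(0.02)


class TestCohort:
    def test_size_and_determinism(self):
        a = make_cohort(34, seed=9)
        b = make_cohort(34, seed=9)
        assert len(a) == 34 and a == b
        assert len({p.seed for p in a}) == 34
        assert all(0 <= p.seed < 2 ** 31 for p in a)

    def test_difficulty_spread(self, small_trials):
        per_pilot = [sum(len(small_trials[i * 2 + j].crash_times)
                         for j in range(2)) for i in range(4)]
        assert per_pilot[-1] > per_pilot[0]
        assert sum(per_pilot) >= 20

    def test_validation(self):
        with pytest.raises(ValueError):
            make_cohort(0)
        with pytest.raises(ValueError):
            PilotParams(sign_error_prob=1.5)
        with pytest.raises(ValueError):
            PilotParams(reaction_delay=-0.1)
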