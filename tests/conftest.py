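"""Shared fixtures: one small simulated cohort reused across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from marscrash.crash_analysis import compute_recoverable_region
from marscrash.dynamics import SimParams
from marscrash.pilot import make_cohort, simulate_cohort
from marscrash import preprocess

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim():
    return SimParams()


@pytest.fixture(scope="session")
def short_sim():
    return SimParams(trial_balance_seconds=30.0)


@pytest.fixture(scope="session")
def small_trials(short_sim):
    """4 pilots x 2 trials of 30 s each: ~47 crashes, ~55 episodes."""
    cohort = make_cohort(4, seed=1)
    return simulate_cohort(cohort, short_sim, 2, seed=1)


@pytest.fixture(scope="session")
def small_episodes(small_trials):
    return preprocess.extract_all_episodes(small_trials)


@pytest.fixture(scope="session")
def small_windows(small_episodes):
    """Windows at the paper's 1000 ms / 800 ms, stride 2 (~4.7k samples)."""
    return preprocess.make_all_windows(small_episodes, 1000.0, 800.0,
                                       stride_steps=2)


@pytest.fixture(scope="session")
def region(sim):
    return compute_recoverable_region(sim)
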