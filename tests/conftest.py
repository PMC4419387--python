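"""Shared fixtures: synthetic trials generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from apakit.model import DEFAULT_THRESHOLDS, Task
from apakit.synth import Population, TrialBlueprint, generate_cohort, generate_trial


@pytest.fixture(scope="session")
def gait_blueprint() -> TrialBlueprint:
    return TrialBlueprint.default(Task.GAIT_INITIATION, seed=42)


@pytest.fixture(scope="session")
def gait_trial(gait_blueprint):
    """One noisy gait-initiation trial (fp, imu, ground truth)."""
    return generate_trial(gait_blueprint)


@pytest.fixture(scope="session")
def gait_trial_noiseless(gait_blueprint):
    return generate_trial(gait_blueprint.noiseless())


@pytest.fixture(scope="session")
def step_trial():
    return generate_trial(TrialBlueprint.default(Task.STEP_CLIMBING, seed=43))


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 2 trials, gait initiation only."""
    return generate_cohort(6, 2, seed=7, tasks=[Task.GAIT_INITIATION])


@pytest.fixture(scope="session")
def thresholds_gait():
    return DEFAULT_THRESHOLDS[Task.GAIT_INITIATION]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
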