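"""Shared fixtures: small scenarios and their fitted pipelines.

Expensive objects (joint distributions, calibrations, deterministic
forward recursions) are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import dynapop as dp


@pytest.fixture(scope="session")
def smoking_scenario():
    return dp.make_synthetic_scenario(dp.ScenarioSpec(preset="smoking_like", seed=1))


@pytest.fixture(scope="session")
def smoking_joint(smoking_scenario):
    return dp.build_joint_distribution(smoking_scenario)


def _pipeline(scenario):
    joint = dp.build_joint_distribution(scenario)
    cp = dp.calibrate_baseline_incidence(scenario, joint)
    schedule = dp.estimate_net_transitions(scenario.risk_factor)
    return scenario, joint, cp, schedule


@pytest.fixture(scope="session")
def mini_pipeline():
    """Two-disease smoking-like scenario (diabetes-like causal parent and
    an acutely-fatal cardiovascular disease) small enough for the dense
    forward recursion."""
    sc = dp.make_synthetic_scenario(
        dp.ScenarioSpec(preset="smoking_like", seed=1, n_diseases=2)
    )
    return _pipeline(sc)


@pytest.fixture(scope="session")
def mini_forward(mini_pipeline):
    sc, joint, cp, schedule = mini_pipeline
    return dp.forward_expectation(sc, cp, schedule)


@pytest.fixture(scope="session")
def causal_pipeline():
    return _pipeline(
        dp.make_synthetic_scenario(dp.ScenarioSpec(preset="causal_pair", seed=3))
    )


@pytest.fixture(scope="session")
def causal_forward(causal_pipeline):
    sc, joint, cp, schedule = causal_pipeline
    return dp.forward_expectation(sc, cp, schedule)


@pytest.fixture(scope="session")
def indep_pipeline():
    return _pipeline(
        dp.make_synthetic_scenario(dp.ScenarioSpec(preset="independent_pair", seed=0))
    )


@pytest.fixture(scope="session")
def indep_forward(indep_pipeline):
    sc, joint, cp, schedule = indep_pipeline
    return dp.forward_expectation(sc, cp, schedule)


@pytest.fixture(scope="session")
def pearce_pipeline():
    return _pipeline(
        dp.make_synthetic_scenario(dp.ScenarioSpec(preset="pearce_ideal", seed=0))
    )


@pytest.fixture(scope="session")
def pearce_forward(pearce_pipeline):
    sc, joint, cp, schedule = pearce_pipeline
    return dp.forward_expectation(sc, cp, schedule)


def make_rate(values_by_sex, name="t"):
    """RateTable from one shared or per-sex list of age values."""
    arr = np.asarray(values_by_sex, dtype=float)
    if arr.ndim == 1:
        arr = np.tile(arr, (2, 1))
    return dp.RateTable(name, arr)
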