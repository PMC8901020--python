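"""Shared fixtures: the calibrated baseline model and cached sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from nephroflow import (
    FeedbackGains,
    KidneyModel,
    SweepSpec,
    load_fixture,
)


@pytest.fixture(scope="session")
def baseline_fixture():
    return load_fixture("baseline")


@pytest.fixture(scope="session")
def baseline_model(baseline_fixture):
    """Healthy closed-loop model calibrated from the packaged fixture."""
    return KidneyModel.from_fixture(baseline_fixture)


@pytest.fixture(scope="session")
def baseline_solution(baseline_model):
    sol = baseline_model.solve()
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def closed_loop_sweep(baseline_model):
    return baseline_model.sweep()


@pytest.fixture(scope="session")
def open_loop_sweep(baseline_model):
    return baseline_model.sweep(SweepSpec(gains=FeedbackGains.open_loop()))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
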