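"""High-level model object tying parameters, calibration and the solver.

:class:`KidneyModel` is the package's front door: build it from a calibrated
fixture (or explicit parameters), solve for a steady state, sweep MAP, apply
disease scenarios, and evaluate the curve against observation tables.

Example
-------
>>> from nephroflow import KidneyModel
>>> model = KidneyModel.from_fixture()
>>> res = model.solve()
>>> round(res.gfr, 1)
120.0
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from . import experiments
from .calibration import calibrated_parameters
from .fixtures import BaselineFixture, load_fixture
from .params import BoundaryConditions, FeedbackGains, KidneyParameters
from .solver import SolverOptions, SteadyStateSolution, solve_steady_state

__all__ = ["KidneyModel"]


@dataclass(frozen=True)
class KidneyModel:
    """A calibrated steady-state kidney model.

    Parameters
    ----------
    params
        Full parameter set (resistances, reabsorption, feedback gains,
        systemic constants).
    boundary
        Default boundary conditions; per-call overrides are accepted by the
        methods.
    """

    params: KidneyParameters
    boundary: BoundaryConditions = field(default_factory=BoundaryConditions)
    options: SolverOptions = field(default_factory=SolverOptions)

    @classmethod
    def from_fixture(
        cls,
        fixture: BaselineFixture | str = "baseline",
        gains: FeedbackGains | None = None,
    ) -> "KidneyModel":
        """Calibrate from a baseline fixture (continuity method)."""
        if not isinstance(fixture, BaselineFixture):
            fixture = load_fixture(fixture)
        params = calibrated_parameters(fixture, gains=gains)
        return cls(params=params, boundary=fixture.boundary_conditions())

    def with_gains(self, gains: FeedbackGains) -> "KidneyModel":
        return replace(self, params=self.params.with_gains(gains))

    def open_loop(self) -> "KidneyModel":
        """Copy with all feedback gains zero."""
        return self.with_gains(FeedbackGains.open_loop())

    def with_scenario(self, scenario: experiments.ScenarioSpec) -> "KidneyModel":
        return replace(self, params=experiments.apply_scenario(self.params, scenario))

    def solve(
        self, map_pressure: float | None = None, **bc_overrides
    ) -> SteadyStateSolution:
        """Solve the steady state, optionally at a non-default MAP."""
        bc = self.boundary
        if map_pressure is not None:
            bc_overrides["map_pressure"] = map_pressure
        if bc_overrides:
            bc = replace(bc, **bc_overrides)
        return solve_steady_state(self.params, bc, self.options)

    def sweep(self, spec: experiments.SweepSpec | None = None) -> experiments.SweepResult:
        return experiments.map_sweep(self.params, spec, self.boundary, self.options)

    def sensitivity(self, **kwargs) -> experiments.SensitivityResult:
        return experiments.sensitivity_grid(self.params, bc=self.boundary, **kwargs)

    def rmse(
        self, obs: pd.DataFrame, spec: experiments.SweepSpec | None = None
    ) -> float:
        """RMSE of the model GFR-MAP curve against an observation table."""
        return experiments.rmse_against_observations(self.sweep(spec), obs)
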