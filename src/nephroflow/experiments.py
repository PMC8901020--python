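"""In-silico experiments: MAP sweeps, feedback ablation, hypertension
scenarios, sensitivity grids, curve interpolation, and RMSE against
observation tables.

A sweep varies MAP (default 54 to 180 mmHg in steps of 9, i.e. 10% of the
90 mmHg baseline) and solves the steady state at each point, warm-starting
each solve from the previous one (continuation) because the myogenic pressure
threshold can stall cold starts. A shape-preserving monotone cubic (PCHIP)
interpolant turns the 15 solved points into a continuous GFR-MAP curve for
comparison against (MAP, GFR) observation tables by root-mean-squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .params import (
    FeedbackGains,
    InvalidParameterError,
    KidneyParameters,
    NodeId,
)
from .solver import SolverOptions, SteadyStateSolution, solve_steady_state
from .params import BoundaryConditions

__all__ = [
    "SweepSpec",
    "ScenarioSpec",
    "SEVERE_HYPERTENSION",
    "BASELINE_SCENARIO",
    "SweepResult",
    "SensitivityResult",
    "map_sweep",
    "apply_scenario",
    "sensitivity_grid",
    "interpolate_curve",
    "rmse_against_observations",
    "validate_ablation",
]


def validate_ablation(gains: FeedbackGains) -> FeedbackGains:
    """Reject ablation combinations the model does not support.

    The ascending myogenic mechanism is not simulated without tubuloglomerular
    feedback: an ascending gain above zero with a zero TGF gain is invalid.
    """
    if gains.myogenic_ascending > 0.0 and gains.tgf == 0.0:
        raise InvalidParameterError(
            "ascending myogenic feedback cannot be enabled with TGF disabled"
        )
    return gains


@dataclass(frozen=True)
class SweepSpec:
    """MAP sweep: range, step (default 10% of the 90 mmHg baseline), gains.

    ``gains`` of None leaves the model's configured gains untouched; an
    explicit value overrides them (the ablation switch).
    """

    map_min: float = 54.0
    map_max: float = 180.0
    step: float = 9.0
    gains: FeedbackGains | None = None

    def __post_init__(self) -> None:
        if not self.map_min < self.map_max:
            raise InvalidParameterError("map_min must be below map_max")
        if self.step <= 0:
            raise InvalidParameterError("step must be positive")
        if self.gains is not None:
            validate_ablation(self.gains)

    @property
    def map_values(self) -> np.ndarray:
        """Grid including both endpoints."""
        n = int(round((self.map_max - self.map_min) / self.step))
        grid = self.map_min + self.step * np.arange(n + 1)
        grid = grid[grid <= self.map_max + 1e-9]
        if grid[-1] < self.map_max - 1e-9:
            grid = np.append(grid, self.map_max)
        return grid


@dataclass(frozen=True)
class ScenarioSpec:
    """Uniform multipliers on vascular resistances and feedback gains.

    ``alpha_resistance`` scales the four vascular resistances (heart-to-
    arteriole, baseline afferent, efferent, efferent-to-vein); tubular
    resistances and the filtration resistance are untouched.
    ``alpha_feedback`` scales all three feedback gains.
    """

    alpha_resistance: float = 1.0
    alpha_feedback: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.alpha_resistance < 0 or self.alpha_feedback < 0:
            raise InvalidParameterError("scenario multipliers must be nonnegative")


#: Severe hypertension: sixfold vascular resistances (a uniform ~0.55 shrink
#: of vessel dimensions), feedback gains halved.
SEVERE_HYPERTENSION = ScenarioSpec(6.0, 0.5, "severe hypertension")
BASELINE_SCENARIO = ScenarioSpec(1.0, 1.0, "baseline")


def apply_scenario(
    params: KidneyParameters, scenario: ScenarioSpec
) -> KidneyParameters:
    """Return a parameter copy with the scenario multipliers applied."""
    if scenario.alpha_resistance <= 0:
        raise InvalidParameterError(
            "resistance multiplier must be positive (resistances must stay > 0)"
        )
    return replace(
        params,
        resistances=params.resistances.with_vascular_scale(scenario.alpha_resistance),
        baseline_afferent_resistance=(
            params.baseline_afferent_resistance * scenario.alpha_resistance
        ),
        feedback_gains=params.feedback_gains.scaled(scenario.alpha_feedback),
    )


@dataclass(frozen=True)
class SweepResult:
    """Solved GFR-MAP curve: one row per MAP with full node state."""

    table: pd.DataFrame
    solutions: tuple[SteadyStateSolution, ...] = field(repr=False)

    @property
    def all_converged(self) -> bool:
        return bool(self.table["converged"].all())

    @property
    def map_values(self) -> np.ndarray:
        return self.table["map_mmHg"].to_numpy()

    @property
    def gfr_values(self) -> np.ndarray:
        return self.table["gfr_ml_min"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _row(sol: SteadyStateSolution) -> dict:
    row = {
        "map_mmHg": sol.boundary.map_pressure,
        "gfr_ml_min": sol.gfr,
        "rpf_ml_min": sol.rpf,
        "urine_flow_ml_min": sol.urine_flow,
        "converged": sol.converged,
        "residual_norm": sol.residual_norm,
        "r_afferent_total": sol.feedback.r_afferent_total,
        "r_tgf": sol.feedback.r_tgf,
        "r_myogenic_descending": sol.feedback.r_myogenic_descending,
        "r_myogenic_ascending": sol.feedback.r_myogenic_ascending,
    }
    for node, p in sol.pressures.items():
        row[f"pressure_{node.value}"] = p
    for node, c in sol.sodium.items():
        row[f"sodium_{node.value}"] = c
    return row


def map_sweep(
    params: KidneyParameters,
    spec: SweepSpec | None = None,
    bc: BoundaryConditions | None = None,
    opts: SolverOptions | None = None,
) -> SweepResult:
    """Solve the steady state over a MAP grid with warm-start continuation.

    A point that fails to converge is kept as a flagged row and the sweep
    continues (the next point restarts cold).
    """
    spec = spec or SweepSpec()
    bc = bc or BoundaryConditions()
    if spec.gains is not None:
        params = params.with_gains(validate_ablation(spec.gains))
    else:
        validate_ablation(params.feedback_gains)
    rows = []
    sols = []
    x_prev = None
    for m in spec.map_values:
        bc_m = replace(bc, map_pressure=float(m))
        sol = solve_steady_state(params, bc_m, opts, x0=x_prev)
        x_prev = sol.x if sol.converged else None
        rows.append(_row(sol))
        sols.append(sol)
    table = pd.DataFrame(rows).sort_values("map_mmHg").reset_index(drop=True)
    return SweepResult(table=table, solutions=tuple(sols))


@dataclass(frozen=True)
class SensitivityResult:
    """One-factor sensitivity grids over resistance and feedback multipliers."""

    resistance_sweeps: dict[float, SweepResult]
    feedback_sweeps: dict[float, SweepResult]
    #: per-node sodium at MAP 90 for each alpha: DataFrame (alpha, node, kind)
    sodium_profiles: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (factor, alpha, MAP)."""
        frames = []
        for kind, sweeps in (
            ("resistance", self.resistance_sweeps),
            ("feedback", self.feedback_sweeps),
        ):
            for alpha, sw in sweeps.items():
                t = sw.table.copy()
                t.insert(0, "alpha", alpha)
                t.insert(0, "factor", kind)
                frames.append(t)
        return pd.concat(frames, ignore_index=True)


def sensitivity_grid(
    params: KidneyParameters,
    resistance_alphas=(1, 2, 4, 6, 8),
    feedback_alphas=(0.0, 0.5, 1.0, 1.5, 2.0),
    spec: SweepSpec | None = None,
    bc: BoundaryConditions | None = None,
    profile_map: float = 90.0,
) -> SensitivityResult:
    """Independent one-factor sweeps over the two scenario multipliers.

    Resistance multipliers run with gains at their configured values;
    feedback multipliers run with resistances at baseline. For each alpha the
    tubular sodium profile at ``profile_map`` mmHg is also recorded.
    """
    spec = spec or SweepSpec()
    bc = bc or BoundaryConditions()
    res_sweeps: dict[float, SweepResult] = {}
    fb_sweeps: dict[float, SweepResult] = {}
    profile_rows = []

    def _profile(sw: SweepResult, factor: str, alpha: float) -> None:
        t = sw.table
        idx = (t["map_mmHg"] - profile_map).abs().idxmin()
        for node in (NodeId.P, NodeId.N, NodeId.K, NodeId.D):
            profile_rows.append(
                {
                    "factor": factor,
                    "alpha": alpha,
                    "map_mmHg": t.loc[idx, "map_mmHg"],
                    "node": node.value,
                    "sodium_meq_per_ml": t.loc[idx, f"sodium_{node.value}"],
                }
            )

    for alpha in resistance_alphas:
        scen = ScenarioSpec(alpha_resistance=float(alpha))
        sw = map_sweep(apply_scenario(params, scen), spec, bc)
        res_sweeps[float(alpha)] = sw
        _profile(sw, "resistance", float(alpha))
    for alpha in feedback_alphas:
        scen = ScenarioSpec(alpha_feedback=float(alpha))
        sw = map_sweep(apply_scenario(params, scen), spec, bc)
        fb_sweeps[float(alpha)] = sw
        _profile(sw, "feedback", float(alpha))
    return SensitivityResult(
        resistance_sweeps=res_sweeps,
        feedback_sweeps=fb_sweeps,
        sodium_profiles=pd.DataFrame(profile_rows),
    )


def interpolate_curve(sweep: SweepResult, map_query: float) -> float:
    """GFR (mL/min) at an arbitrary MAP inside the sweep range.

    Shape-preserving monotone cubic (PCHIP) through the solved (MAP, GFR)
    knots: exact at knots, no spurious oscillation, no silent extrapolation.
    """
    maps = sweep.map_values
    if not (maps[0] <= map_query <= maps[-1]):
        raise InvalidParameterError(
            f"MAP {map_query} outside sweep range [{maps[0]}, {maps[-1]}]"
        )
    interp = PchipInterpolator(maps, sweep.gfr_values)
    return float(interp(map_query))


def rmse_against_observations(sweep: SweepResult, obs: pd.DataFrame) -> float:
    """Root-mean-squared error of the model curve against (MAP, GFR) rows.

    ``obs`` needs columns ``map_mmHg`` and ``gfr_ml_min``; every observation
    MAP must lie inside the sweep range.
    """
    if len(obs) == 0:
        raise InvalidParameterError("observation table is empty")
    missing = {"map_mmHg", "gfr_ml_min"} - set(obs.columns)
    if missing:
        raise InvalidParameterError(f"observation table missing columns {missing}")
    maps = sweep.map_values
    interp = PchipInterpolator(maps, sweep.gfr_values)
    m = obs["map_mmHg"].to_numpy(dtype=float)
    if m.min() < maps[0] or m.max() > maps[-1]:
        raise InvalidParameterError("observations outside the sweep MAP range")
    pred = interp(m)
    err = obs["gfr_ml_min"].to_numpy(dtype=float) - pred
    return float(np.sqrt(np.mean(err**2)))
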