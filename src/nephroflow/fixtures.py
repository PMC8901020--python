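"""Versioned baseline constants and the synthetic observation generator.

Every numeric constant of the healthy baseline (boundary conditions,
prescribed calibration pressures, vessel geometry, external reference flows)
lives in one structured-text fixture shipped with the package, so tests and
experiments share a single source of truth. A small generator produces
seeded synthetic (MAP, GFR) observation tables from a model curve, standing
in for patient data in the RMSE machinery.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .params import (
    AXIAL_BLOOD_CHAIN,
    FILTRATE_CHAIN,
    BoundaryConditions,
    InvalidParameterError,
    NodeId,
    SystemicParameters,
)

__all__ = [
    "BaselineFixture",
    "FixtureError",
    "load_fixture",
    "SyntheticObservationSpec",
    "generate_observations",
]


class FixtureError(ValueError):
    """The fixture file is missing, malformed, or violates an invariant."""


@dataclass(frozen=True)
class BaselineFixture:
    """Parsed and validated baseline fixture."""

    name: str
    constants: dict[str, float]
    pressures: dict[NodeId, float]
    geometry: dict[str, dict[str, float]]
    scaling_bounds: tuple[float, float]
    reference_flows: dict[str, float]
    raw: dict

    def boundary_conditions(self) -> BoundaryConditions:
        c = self.constants
        return BoundaryConditions(
            map_pressure=c["map_mmHg"],
            ureter_pressure=c["ureter_pressure_mmHg"],
            venous_pressure=c["venous_pressure_mmHg"],
            venous_sodium=c["venous_sodium_meq_per_ml"],
        )

    def systemic_parameters(self) -> SystemicParameters:
        c = self.constants
        return SystemicParameters(
            cardiac_output=c["cardiac_output_ml_min"],
            kidney_flow_fraction=c["kidney_flow_fraction"],
            plasma_fraction=c["plasma_fraction"],
            nephron_scale=c["nephron_scale"],
        )

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=False))


_REQUIRED_CONSTANTS = (
    "map_mmHg", "ureter_pressure_mmHg", "venous_pressure_mmHg",
    "venous_sodium_meq_per_ml", "cardiac_output_ml_min",
    "kidney_flow_fraction", "plasma_fraction", "nephron_scale",
    "oncotic_pressure_mmHg", "filtration_resistance",
    "baseline_afferent_resistance", "heart_to_arteriole_drop_mmHg",
    "gfr_target_ml_min", "resistance_unit",
)


def _validate(raw: Mapping) -> BaselineFixture:
    try:
        constants = {k: float(raw["constants"][k]) for k in _REQUIRED_CONSTANTS}
        pressures = {NodeId(k): float(v) for k, v in raw["pressures_mmHg"].items()}
        geometry = {
            str(k): {f: float(v[f]) for f in ("length_cm", "radius_cm", "viscosity_mmHg_s")}
            for k, v in raw["geometry"].items()
        }
        lo, hi = (float(b) for b in raw["scaling_bounds"])
        reference = {str(k): float(v) for k, v in raw["reference_flows"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise FixtureError(f"malformed fixture: {exc!r}") from exc

    missing = {n for n in NodeId} - set(pressures)
    if missing:
        raise FixtureError(f"fixture pressures missing nodes {sorted(missing)}")
    # monotone non-increasing along each flow chain
    for chain in (AXIAL_BLOOD_CHAIN, FILTRATE_CHAIN):
        vals = [pressures[n] for n in chain]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise FixtureError(
                f"pressures not monotone along chain {'-'.join(n.value for n in chain)}"
            )
    for seg, g in geometry.items():
        if g["length_cm"] <= 0 or g["radius_cm"] <= 0 or g["viscosity_mmHg_s"] <= 0:
            raise FixtureError(f"segment {seg}: geometry must be strictly positive")
    if not (0.0 < lo < 1.0 <= hi):
        raise FixtureError("scaling bounds must straddle 1")
    if any(v <= 0 for v in reference.values()):
        raise FixtureError("reference flows must be positive")
    return BaselineFixture(
        name=str(raw.get("name", "unnamed")),
        constants=constants,
        pressures=pressures,
        geometry=geometry,
        scaling_bounds=(lo, hi),
        reference_flows=reference,
        raw=dict(raw),
    )


def load_fixture(name_or_path: str | Path = "baseline") -> BaselineFixture:
    """Load a fixture by packaged name (``"baseline"``) or file path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        resource = importlib.resources.files("nephroflow.data") / f"{name_or_path}.yaml"
        try:
            text = resource.read_text()
        except FileNotFoundError as exc:
            raise FixtureError(f"no fixture named or at {name_or_path!r}") from exc
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise FixtureError("fixture file does not hold a mapping")
    return _validate(raw)


@dataclass(frozen=True)
class SyntheticObservationSpec:
    """Recipe for a synthetic (MAP, GFR) observation table.

    ``map_values`` are sampled (with replacement when ``n`` exceeds their
    count) and Gaussian noise of standard deviation ``noise_sd`` (mL/min) is
    added to the model curve; the seed is mandatory for reproducibility.
    """

    map_values: tuple[float, ...]
    noise_sd: float
    n: int
    seed: int
    subject: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        if not self.map_values:
            raise InvalidParameterError("map_values must be non-empty")


def generate_observations(spec: SyntheticObservationSpec, sweep) -> "pd.DataFrame":
    """Sample noisy observations from a model GFR-MAP curve.

    Parameters
    ----------
    sweep : SweepResult
        A solved MAP sweep; queried through its spline interpolant, so every
        sampled MAP must lie inside the sweep range.

    Returns a DataFrame with columns ``map_mmHg``, ``gfr_ml_min`` (and
    ``subject`` when labelled), suitable for
    :func:`nephroflow.experiments.rmse_against_observations`.
    """
    import pandas as pd

    from .experiments import interpolate_curve

    rng = np.random.default_rng(spec.seed)
    maps = rng.choice(np.asarray(spec.map_values, dtype=float), size=spec.n)
    gfr = np.array([interpolate_curve(sweep, m) for m in maps])
    gfr = gfr + rng.normal(0.0, spec.noise_sd, size=spec.n)
    table = pd.DataFrame({"map_mmHg": maps, "gfr_ml_min": gfr})
    if spec.subject is not None:
        table["subject"] = spec.subject
    return table
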