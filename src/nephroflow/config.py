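"""Run configuration: a validated YAML schema for the command line.

A config names exactly one resistance source (``fixture`` | ``explicit`` |
``geometry``), the boundary/systemic overrides, feedback gains, an optional
scenario, the experiment to run, output paths and a seed. Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import VesselGeometry, calibrated_parameters
from .experiments import ScenarioSpec, SweepSpec, apply_scenario, validate_ablation
from .fixtures import load_fixture
from .model import KidneyModel
from .params import (
    BoundaryConditions,
    FeedbackGains,
    KidneyParameters,
    ResistanceSet,
    SystemicParameters,
)

__all__ = ["RunConfig", "ConfigError", "load_config"]

EXPERIMENTS = ("solve", "sweep", "sensitivity", "calibrate", "fit-obs", "make-synth")


class ConfigError(ValueError):
    """The configuration violates the schema; the message names the key."""


_TOP_KEYS = {
    "experiment", "fixture", "boundary", "systemic", "resistances", "gains",
    "scenario", "sweep", "observations", "synthetic", "out", "seed", "verbose",
}
_BOUNDARY_KEYS = {"map": "map_pressure", "ureter": "ureter_pressure",
                  "venous": "venous_pressure", "venous_sodium": "venous_sodium"}
_SYSTEMIC_KEYS = {"cardiac_output", "kidney_flow_fraction", "plasma_fraction",
                  "nephron_scale"}
_GAIN_KEYS = {"tgf": "tgf", "md": "myogenic_descending", "ma": "myogenic_ascending"}
_SCENARIO_KEYS = {"alpha_resistance", "alpha_feedback", "preset"}
_SWEEP_KEYS = {"map_min", "map_max", "step"}
_SYNTH_KEYS = {"map_values", "noise_sd", "n", "subject"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration."""

    experiment: str
    model: KidneyModel
    sweep_spec: SweepSpec
    scenario: ScenarioSpec | None
    observations_path: Path | None
    synthetic: dict | None
    out: Path | None
    seed: int
    verbose: int
    raw: dict = field(repr=False)


def _build_boundary(raw: dict, defaults: BoundaryConditions) -> BoundaryConditions:
    _check_keys(raw, set(_BOUNDARY_KEYS), "boundary")
    kwargs = {dest: float(raw[src]) for src, dest in _BOUNDARY_KEYS.items() if src in raw}
    from dataclasses import replace

    return replace(defaults, **kwargs)


def _build_gains(raw: dict) -> FeedbackGains:
    _check_keys(raw, set(_GAIN_KEYS), "gains")
    kwargs = {dest: float(raw[src]) for src, dest in _GAIN_KEYS.items() if src in raw}
    return validate_ablation(FeedbackGains(**kwargs))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Baseline defaults (MAP 90, ureter 0, venous 3, venous sodium 0.140,
    fixture-calibrated resistances, gains of one) apply where keys are
    omitted; schema violations raise :class:`ConfigError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    experiment = str(raw.get("experiment", "solve"))
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            f"experiment must be one of {EXPERIMENTS}, got {experiment!r}"
        )

    fixture = load_fixture(raw.get("fixture", "baseline"))
    boundary = _build_boundary(raw.get("boundary", {}) or {}, fixture.boundary_conditions())
    gains = _build_gains(raw.get("gains", {}) or {})

    systemic_raw = raw.get("systemic", {}) or {}
    _check_keys(systemic_raw, _SYSTEMIC_KEYS, "systemic")

    res_raw = raw.get("resistances", {}) or {}
    sources = [k for k in ("fixture", "explicit", "geometry") if k in res_raw]
    _check_keys(res_raw, {"fixture", "explicit", "geometry"}, "resistances")
    if len(sources) > 1:
        raise ConfigError(
            f"exactly one resistance source allowed, got {sources} in resistances"
        )

    if sources and sources[0] == "explicit":
        try:
            rset = ResistanceSet(**{f"r_{k}": float(v) for k, v in res_raw["explicit"].items()})
        except TypeError as exc:
            raise ConfigError(f"bad explicit resistances: {exc}") from exc
        sysm = fixture.systemic_parameters()
        if systemic_raw:
            from dataclasses import replace as _rep

            sysm = _rep(sysm, **{k: float(v) for k, v in systemic_raw.items()})
        params = KidneyParameters(
            resistances=rset,
            oncotic_pressure_GB=fixture.constants["oncotic_pressure_mmHg"],
            baseline_afferent_resistance=fixture.constants["baseline_afferent_resistance"],
            feedback_gains=gains,
            systemic=sysm,
        )
        model = KidneyModel(params=params, boundary=boundary)
    elif sources and sources[0] == "geometry":
        geom = VesselGeometry.from_fixture_geometry(res_raw["geometry"])
        # geometry source: Poiseuille resistances at the configured scalings
        r = geom.resistances()
        try:
            rset = ResistanceSet(
                r_HA=r["HA"], r_GE=r["GE"], r_EV=r["EV"], r_BP=r["BP"],
                r_PN=r["PN"], r_NK=r["NK"], r_KD=r["KD"], r_DU=r["DU"],
                r_GB=fixture.constants["filtration_resistance"],
            )
        except KeyError as exc:
            raise ConfigError(f"geometry source missing segment {exc}") from exc
        params = KidneyParameters(
            resistances=rset,
            oncotic_pressure_GB=fixture.constants["oncotic_pressure_mmHg"],
            baseline_afferent_resistance=fixture.constants["baseline_afferent_resistance"],
            feedback_gains=gains,
            systemic=fixture.systemic_parameters(),
        )
        model = KidneyModel(params=params, boundary=boundary)
    else:
        params = calibrated_parameters(fixture, gains=gains)
        from dataclasses import replace as _rep

        if systemic_raw:
            params = _rep(
                params,
                systemic=_rep(
                    params.systemic, **{k: float(v) for k, v in systemic_raw.items()}
                ),
            )
        model = KidneyModel(params=params, boundary=boundary)

    scenario = None
    if "scenario" in raw and raw["scenario"]:
        s = raw["scenario"]
        _check_keys(s, _SCENARIO_KEYS, "scenario")
        if "preset" in s:
            from .experiments import BASELINE_SCENARIO, SEVERE_HYPERTENSION

            presets = {"baseline": BASELINE_SCENARIO,
                       "severe-hypertension": SEVERE_HYPERTENSION}
            if s["preset"] not in presets:
                raise ConfigError(f"unknown scenario preset {s['preset']!r}")
            scenario = presets[s["preset"]]
        else:
            scenario = ScenarioSpec(
                alpha_resistance=float(s.get("alpha_resistance", 1.0)),
                alpha_feedback=float(s.get("alpha_feedback", 1.0)),
            )
        model = model.with_scenario(scenario)

    sweep_raw = raw.get("sweep", {}) or {}
    _check_keys(sweep_raw, _SWEEP_KEYS, "sweep")
    sweep_spec = SweepSpec(
        map_min=float(sweep_raw.get("map_min", 54.0)),
        map_max=float(sweep_raw.get("map_max", 180.0)),
        step=float(sweep_raw.get("step", 9.0)),
        gains=model.params.feedback_gains,
    )

    obs_path = None
    if "observations" in raw and raw["observations"]:
        obs_path = Path(raw["observations"])
        if not obs_path.exists():
            raise ConfigError(f"observations file {obs_path} does not exist")

    synth = None
    if "synthetic" in raw and raw["synthetic"]:
        _check_keys(raw["synthetic"], _SYNTH_KEYS, "synthetic")
        synth = dict(raw["synthetic"])

    return RunConfig(
        experiment=experiment,
        model=model,
        sweep_spec=sweep_spec,
        scenario=scenario,
        observations_path=obs_path,
        synthetic=synth,
        out=Path(raw["out"]) if raw.get("out") else None,
        seed=int(raw.get("seed", 0)),
        verbose=int(raw.get("verbose", 0)),
        raw=raw,
    )
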