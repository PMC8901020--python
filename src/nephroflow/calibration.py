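"""Resistance calibration.

Two routes to the edge resistances:

* **continuity (method 2)** — prescribe a physiological pressure at every
  node and a whole-body GFR target, forward-propagate the flows through the
  reabsorption fractions, and read each edge resistance off as dP/Q. The
  afferent value obtained this way is the *feedback-modulated total*; the
  feedback-free baseline R_b is a separate literature constant.
* **Poiseuille (method 1)** — compute each resistance from vessel length,
  radius and viscosity, with per-segment dimensionless scaling factors on
  length and radius fitted by bounded least squares so method 1 reproduces
  the method-2 targets. The fit is overparameterized (two scalings per
  segment, one resistance target), so near-exact feasible solutions exist;
  feasibility is what matters, not a unique optimum.

The heart-to-arteriole resistance is derived separately from the prescribed
13 mmHg perfusion drop and the baseline renal plasma flow, so that renal
inflow can respond to MAP in simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .feedback import afferent_resistance
from .params import (
    FeedbackGains,
    InvalidParameterError,
    KidneyParameters,
    NodeId,
    ReabsorptionRules,
    ResistanceSet,
    SystemicParameters,
    aggregate_flow,
    per_nephron_flow,
)
from .physics import (
    poiseuille_resistance,
    sodium_reabsorption_fraction,
    water_reabsorption_fraction,
)

__all__ = [
    "ContinuityCalibration",
    "VesselGeometry",
    "GeometryFitReport",
    "resistances_from_continuity",
    "derive_heart_to_arteriole_resistance",
    "fit_geometry_scalings",
    "calibrated_parameters",
]


@dataclass(frozen=True)
class ContinuityCalibration:
    """Output of the continuity (method-2) calibration."""

    resistances: ResistanceSet
    #: feedback-modulated afferent total implied by the prescribed pressures
    r_afferent_total: float
    #: per-nephron flows used in the derivation (mL/s), keyed by edge
    flows: dict[str, float]
    #: tubular sodium concentrations at the prescribed state (mEq/mL)
    sodium: dict[NodeId, float]


def resistances_from_continuity(
    pressures: dict[NodeId, float],
    gfr_target: float,
    systemic: SystemicParameters,
    reabsorption: ReabsorptionRules | None = None,
    r_GB: float = 1.0e7,
    venous_sodium: float = 0.140,
) -> ContinuityCalibration:
    """Derive all edge resistances from a prescribed pressure profile.

    Flows are forward-propagated per nephron from the GFR target and the
    baseline plasma inflow; each edge resistance is then dP/Q. The filtration
    resistance ``r_GB`` is an input and is passed through unchanged.
    """
    if gfr_target <= 0:
        raise InvalidParameterError("GFR target must be positive")
    rules = reabsorption or ReabsorptionRules()
    P = pressures

    q_GB = per_nephron_flow(gfr_target, systemic)  # filtration, mL/s
    q_AG = systemic.per_nephron_plasma_flow
    q_GE = q_AG - q_GB
    q_BP = q_GB
    q_PN = (1.0 - rules.water_fraction_P) * q_BP
    r_N = water_reabsorption_fraction(
        NodeId.N, aggregate_flow(q_PN, systemic), rules
    )
    q_NK = (1.0 - r_N) * q_PN
    q_KD = q_NK
    q_DU = (1.0 - rules.water_fraction_D) * q_KD
    flows = {
        "HA": q_AG, "AG": q_AG, "GB": q_GB, "GE": q_GE, "EV": q_GE,
        "BP": q_BP, "PN": q_PN, "NK": q_NK, "KD": q_KD, "DU": q_DU,
    }
    edges = {
        "HA": (NodeId.H, NodeId.A),
        "AG": (NodeId.A, NodeId.G),
        "GE": (NodeId.G, NodeId.E),
        "EV": (NodeId.E, NodeId.V),
        "BP": (NodeId.B, NodeId.P),
        "PN": (NodeId.P, NodeId.N),
        "NK": (NodeId.N, NodeId.K),
        "KD": (NodeId.K, NodeId.D),
        "DU": (NodeId.D, NodeId.U),
    }
    r = {}
    for edge, (up, down) in edges.items():
        q = flows[edge]
        if q == 0.0:
            raise InvalidParameterError(
                f"edge {edge}: zero flow, resistance undefined"
            )
        r[edge] = (P[up] - P[down]) / q

    # tubular sodium at the prescribed state (concentration balance)
    c_P = venous_sodium * (1.0 - rules.sodium_fraction_P) * q_BP / q_PN
    c_N = c_P * q_PN / q_NK
    c_K = (1.0 - rules.sodium_fraction_K) * q_NK * c_N / q_KD
    j_KD = q_KD * c_K
    r_D = sodium_reabsorption_fraction(
        NodeId.D, aggregate_flow(j_KD, systemic), rules
    )
    c_D = (1.0 - r_D) * j_KD / q_DU

    resistances = ResistanceSet(
        r_HA=r["HA"], r_GE=r["GE"], r_EV=r["EV"], r_BP=r["BP"],
        r_PN=r["PN"], r_NK=r["NK"], r_KD=r["KD"], r_DU=r["DU"], r_GB=r_GB,
    )
    return ContinuityCalibration(
        resistances=resistances,
        r_afferent_total=r["AG"],
        flows=flows,
        sodium={NodeId.P: c_P, NodeId.N: c_N, NodeId.K: c_K, NodeId.D: c_D},
    )


def derive_heart_to_arteriole_resistance(
    pressure_drop: float, systemic: SystemicParameters
) -> float:
    """Heart-to-arteriole resistance from the perfusion pressure drop.

    The per-nephron baseline plasma flow is CO * kidney fraction * 2 kidneys
    * plasma fraction / nephron count (mL/s); the resistance is drop / flow.
    """
    if pressure_drop <= 0:
        raise InvalidParameterError("pressure drop must be positive")
    flow = systemic.per_nephron_plasma_flow
    if flow <= 0:
        raise InvalidParameterError("baseline plasma flow must be positive")
    return pressure_drop / flow


@dataclass(frozen=True)
class VesselGeometry:
    """Per-segment baseline dimensions (cm), viscosity (mmHg*s) and scalings."""

    lengths: dict[str, float]
    radii: dict[str, float]
    viscosities: dict[str, float]
    length_scalings: dict[str, float]
    radius_scalings: dict[str, float]

    @classmethod
    def from_fixture_geometry(
        cls, geometry: dict[str, dict[str, float]]
    ) -> "VesselGeometry":
        segs = list(geometry)
        return cls(
            lengths={s: geometry[s]["length_cm"] for s in segs},
            radii={s: geometry[s]["radius_cm"] for s in segs},
            viscosities={s: geometry[s]["viscosity_mmHg_s"] for s in segs},
            length_scalings={s: 1.0 for s in segs},
            radius_scalings={s: 1.0 for s in segs},
        )

    @property
    def segments(self) -> list[str]:
        return list(self.lengths)

    def resistances(self) -> dict[str, float]:
        """Poiseuille (method-1) resistance per segment at current scalings."""
        return {
            s: poiseuille_resistance(
                self.viscosities[s],
                self.lengths[s] * self.length_scalings[s],
                self.radii[s] * self.radius_scalings[s],
            )
            for s in self.segments
        }

    def with_scalings(
        self, length_scalings: dict[str, float], radius_scalings: dict[str, float]
    ) -> "VesselGeometry":
        return replace(
            self,
            length_scalings=dict(length_scalings),
            radius_scalings=dict(radius_scalings),
        )


@dataclass(frozen=True)
class GeometryFitReport:
    """Result of the bounded least-squares geometry fit."""

    geometry: VesselGeometry
    target_resistances: dict[str, float]
    fitted_resistances: dict[str, float]
    average_percent_error: float
    cost: float
    success: bool
    message: str

    def optimized_dimensions(self) -> dict[str, tuple[float, float]]:
        g = self.geometry
        return {
            s: (
                g.lengths[s] * g.length_scalings[s],
                g.radii[s] * g.radius_scalings[s],
            )
            for s in g.segments
        }


def fit_geometry_scalings(
    geometry: VesselGeometry,
    targets: dict[str, float],
    bounds: tuple[float, float] = (0.7, 1.2),
) -> GeometryFitReport:
    """Fit per-segment length/radius scalings so Poiseuille matches targets.

    Bounded least squares on the relative resistance mismatch, starting from
    unit scalings. One target per segment against two scalings leaves a
    one-dimensional family of exact solutions whenever the needed resistance
    ratio is reachable within the bounds, so any feasible point is accepted.
    Unreachable targets produce a report with a large residual, not an
    exception.
    """
    segs = [s for s in geometry.segments if s in targets]
    if not segs:
        raise InvalidParameterError("no overlapping segments between geometry and targets")
    lo, hi = bounds
    base = geometry.resistances()

    def residual(z: np.ndarray) -> np.ndarray:
        sl, sr = z[: len(segs)], z[len(segs):]
        out = np.empty(len(segs))
        for i, s in enumerate(segs):
            # R(s_l, s_r) = R_base * s_l / s_r^4
            r = base[s] * sl[i] / sr[i] ** 4
            out[i] = r / targets[s] - 1.0
        return out

    z0 = np.ones(2 * len(segs))
    result = least_squares(
        residual,
        z0,
        bounds=(lo, hi),
        xtol=3e-16,
        ftol=3e-16,
        gtol=1e-15,
        method="trf",
    )
    sl = {s: float(result.x[i]) for i, s in enumerate(segs)}
    sr = {s: float(result.x[len(segs) + i]) for i, s in enumerate(segs)}
    fitted_geom = geometry.with_scalings(
        {**geometry.length_scalings, **sl}, {**geometry.radius_scalings, **sr}
    )
    fitted = {s: fitted_geom.resistances()[s] for s in segs}
    avg_pct = float(
        np.mean([abs(fitted[s] - targets[s]) / targets[s] for s in segs]) * 100.0
    )
    return GeometryFitReport(
        geometry=fitted_geom,
        target_resistances={s: targets[s] for s in segs},
        fitted_resistances=fitted,
        average_percent_error=avg_pct,
        cost=float(result.cost),
        success=bool(result.success),
        message=str(result.message),
    )


def calibrated_parameters(
    fixture,
    gains: FeedbackGains | None = None,
    *,
    consistency_rtol: float = 0.02,
) -> KidneyParameters:
    """Build the calibrated healthy parameter set from a baseline fixture.

    Runs the continuity calibration on the fixture's prescribed pressures and
    checks that the feedback relations, evaluated at the prescribed state,
    reproduce the continuity-derived afferent total within
    ``consistency_rtol`` (a consistency check on the calibration, not a
    fitted parameter).
    """
    c = fixture.constants
    systemic = fixture.systemic_parameters()
    calib = resistances_from_continuity(
        fixture.pressures,
        c["gfr_target_ml_min"],
        systemic,
        r_GB=c["filtration_resistance"],
        venous_sodium=c["venous_sodium_meq_per_ml"],
    )
    r_b = c["baseline_afferent_resistance"]
    fb = afferent_resistance(
        r_b,
        fixture.pressures[NodeId.A],
        calib.sodium[NodeId.D],
        calib.resistances.r_GE,
        FeedbackGains(),
    )
    rel = abs(fb.r_afferent_total - calib.r_afferent_total) / calib.r_afferent_total
    if rel > consistency_rtol:
        raise InvalidParameterError(
            "feedback relations do not reproduce the continuity-derived "
            f"afferent resistance (relative mismatch {rel:.3%})"
        )
    return KidneyParameters(
        resistances=calib.resistances,
        oncotic_pressure_GB=c["oncotic_pressure_mmHg"],
        baseline_afferent_resistance=r_b,
        feedback_gains=gains or FeedbackGains(),
        systemic=systemic,
    )
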