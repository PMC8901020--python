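"""Domain types and unit conventions for the lumped nephron network.

The kidney is discretized into eleven anatomical nodes. Blood enters from the
heart ``H`` through the pre-afferent arteriole ``A`` into the glomerulus ``G``;
filtrate passes through Bowman's space ``B``, the proximal tubule ``P``, the
thin descending limb ``N``, the thick ascending limb ``K`` and the lumped
distal tubule / collecting duct ``D`` to the ureter ``U``; blood continues
from ``G`` through the post-efferent arteriole ``E`` to the veins ``V``.
Reabsorption edges return fluid and sodium from P, N, D (water) and P, K, D
(sodium) to ``V``.

Unit conventions
----------------
* pressures: mmHg
* per-nephron flows: mL/s; sodium fluxes: mEq/s
* resistances: mmHg*s/mL (the literature prints the same numerals as
  "s/mL/mmHg"; dimensional analysis of dP/Q fixes mmHg*s/mL)
* sodium concentrations: mEq/mL (venous sodium 140 mEq/L = 0.140 mEq/mL)
* whole-body outputs (GFR, RPF, urine flow): mL/min, obtained by scaling one
  representative nephron by ``nephron_scale`` (2e6, both kidneys) and by 60.

The empirical reabsorption and feedback relations are calibrated on
*aggregate* quantities (mL/min, mEq/min) and on a normalized resistance unit
``RESISTANCE_UNIT`` = 1e7 mmHg*s/mL; see :mod:`nephroflow.physics` and
:mod:`nephroflow.feedback`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable

__all__ = [
    "NodeId",
    "AXIAL_BLOOD_CHAIN",
    "FILTRATE_CHAIN",
    "RESISTANCE_UNIT",
    "InvalidParameterError",
    "InvalidNodeError",
    "NodeState",
    "BoundaryConditions",
    "SystemicParameters",
    "FeedbackGains",
    "ResistanceSet",
    "ReabsorptionRules",
    "KidneyParameters",
    "FlowSet",
    "aggregate_flow",
    "per_nephron_flow",
]

#: Normalized resistance unit in which the feedback relations are expressed.
#: The filtration resistance R_GB is exactly 1.0 in this unit.
RESISTANCE_UNIT: float = 1.0e7


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (sign, range, finiteness)."""


class InvalidNodeError(KeyError):
    """A node identifier is outside the set an operation accepts."""


class NodeId(str, enum.Enum):
    """Anatomical node identifiers; the set and topology are fixed."""

    H = "H"  # heart (MAP boundary)
    A = "A"  # pre-afferent arteriole
    G = "G"  # glomerulus
    B = "B"  # Bowman's space
    P = "P"  # proximal tubule
    N = "N"  # thin descending limb of Henle
    K = "K"  # thick ascending limb of Henle
    D = "D"  # distal tubule + collecting duct (lumped)
    E = "E"  # post-efferent arteriole
    V = "V"  # veins (boundary)
    U = "U"  # ureter (boundary)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Axial blood chain H -> A -> G -> E -> V.
AXIAL_BLOOD_CHAIN = (NodeId.H, NodeId.A, NodeId.G, NodeId.E, NodeId.V)
#: Filtrate chain G -> B -> P -> N -> K -> D -> U.
FILTRATE_CHAIN = (
    NodeId.G,
    NodeId.B,
    NodeId.P,
    NodeId.N,
    NodeId.K,
    NodeId.D,
    NodeId.U,
)

#: Tubular nodes with a water / sodium reabsorption fraction.
TUBULAR_NODES = (NodeId.P, NodeId.N, NodeId.K, NodeId.D)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class NodeState:
    """Hydraulic pressure (mmHg) and sodium concentration (mEq/mL) at a node."""

    pressure: float
    sodium_concentration: float = 0.0

    def __post_init__(self) -> None:
        import math

        _require(math.isfinite(self.pressure), "pressure must be finite")
        _require(
            self.sodium_concentration >= 0.0,
            "sodium concentration must be nonnegative",
        )


@dataclass(frozen=True)
class BoundaryConditions:
    """Fixed inputs of the model: MAP, ureter/venous pressures, venous sodium.

    Healthy baseline: MAP 90 mmHg, ureter 0 mmHg, veins 3 mmHg, venous sodium
    0.140 mEq/mL. Bowman's-space sodium equals venous sodium (free filtration).
    """

    map_pressure: float = 90.0
    ureter_pressure: float = 0.0
    venous_pressure: float = 3.0
    venous_sodium: float = 0.140

    def __post_init__(self) -> None:
        _require(self.venous_sodium >= 0.0, "venous sodium must be nonnegative")


@dataclass(frozen=True)
class SystemicParameters:
    """Whole-body constants tying one representative nephron to the body.

    One tenth of cardiac output perfuses each kidney; 55% of blood flow is
    plasma; the representative nephron is scaled by 2e6 (both kidneys).
    """

    cardiac_output: float = 5500.0  # mL/min
    kidney_flow_fraction: float = 0.1
    plasma_fraction: float = 0.55
    nephron_scale: float = 2.0e6

    def __post_init__(self) -> None:
        _require(self.cardiac_output > 0, "cardiac output must be positive")
        _require(
            0.0 < self.kidney_flow_fraction <= 1.0,
            "kidney flow fraction must lie in (0, 1]",
        )
        _require(
            0.0 < self.plasma_fraction <= 1.0,
            "plasma fraction must lie in (0, 1]",
        )
        _require(self.nephron_scale > 0, "nephron scale must be positive")

    @property
    def per_nephron_plasma_flow(self) -> float:
        """Baseline plasma inflow per nephron in mL/s (both kidneys pooled)."""
        total = (
            self.cardiac_output
            * self.kidney_flow_fraction
            * 2.0
            * self.plasma_fraction
        )  # mL/min, both kidneys
        return total / self.nephron_scale / 60.0


@dataclass(frozen=True)
class FeedbackGains:
    """Multipliers on the three autoregulation mechanisms.

    All ones for a healthy subject; all zeros opens the loop (afferent
    resistance collapses to its baseline value).
    """

    tgf: float = 1.0
    myogenic_descending: float = 1.0
    myogenic_ascending: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tgf", "myogenic_descending", "myogenic_ascending"):
            _require(getattr(self, name) >= 0.0, f"gain {name} must be >= 0")

    def scaled(self, alpha: float) -> "FeedbackGains":
        _require(alpha >= 0.0, "feedback multiplier must be nonnegative")
        return FeedbackGains(
            self.tgf * alpha,
            self.myogenic_descending * alpha,
            self.myogenic_ascending * alpha,
        )

    @classmethod
    def open_loop(cls) -> "FeedbackGains":
        return cls(0.0, 0.0, 0.0)


_EDGES = ("HA", "GB", "GE", "EV", "BP", "PN", "NK", "KD", "DU")


@dataclass(frozen=True)
class ResistanceSet:
    """One hydraulic resistance per fixed edge, in mmHg*s/mL.

    The afferent edge A->G is not stored here: its total resistance is the
    baseline value plus feedback contributions, evaluated by
    :mod:`nephroflow.feedback`. The filtration resistance ``r_GB`` is fixed at
    1e7 mmHg*s/mL.
    """

    r_HA: float
    r_GE: float
    r_EV: float
    r_BP: float
    r_PN: float
    r_NK: float
    r_KD: float
    r_DU: float
    r_GB: float = 1.0e7

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _require(getattr(self, name) > 0.0, f"resistance {name} must be > 0")

    def with_vascular_scale(self, alpha: float) -> "ResistanceSet":
        """Scale the vascular resistances (H-A, G-E, E-V) by ``alpha``.

        The afferent baseline is scaled alongside in
        :meth:`KidneyParameters.with_scenario`; tubular resistances and the
        filtration resistance are untouched.
        """
        _require(alpha > 0.0, "resistance multiplier must be positive")
        return replace(
            self,
            r_HA=self.r_HA * alpha,
            r_GE=self.r_GE * alpha,
            r_EV=self.r_EV * alpha,
        )


@dataclass(frozen=True)
class ReabsorptionRules:
    """Water and sodium reabsorption fractions along the tubule.

    Constants reflect fixed hormone levels: proximal glomerulotubular balance
    (0.75 for both water and sodium), ADH-set distal water reabsorption
    (0.95), aldosterone-modulated distal sodium reabsorption (inverse sigmoid
    of sodium delivery), and a constant 0.80 sodium fraction at the thick
    ascending limb. The descending limb is sodium-impermeable; the ascending
    limb is water-impermeable.
    """

    water_fraction_P: float = 0.75
    water_fraction_D: float = 0.95
    sodium_fraction_P: float = 0.75
    sodium_fraction_K: float = 0.80
    # Empirical coefficients, fitted on aggregate units (mL/min, mEq/min):
    # r_N^w = descending_intercept - descending_slope * Q_PN[mL/min]
    descending_intercept: float = 0.65
    descending_slope: float = 0.01
    # r_D^Na = distal_amplitude / (1 + exp(distal_rate*J_KD[mEq/min]
    #          - distal_shift)) + distal_floor
    distal_amplitude: float = 0.2268
    distal_rate: float = 7.0
    distal_shift: float = 7.7
    distal_floor: float = 0.7316

    def __post_init__(self) -> None:
        for name in ("water_fraction_P", "water_fraction_D",
                     "sodium_fraction_P", "sodium_fraction_K"):
            v = getattr(self, name)
            _require(0.0 <= v < 1.0, f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class KidneyParameters:
    """Full parameter set of the model."""

    resistances: ResistanceSet
    reabsorption: ReabsorptionRules = field(default_factory=ReabsorptionRules)
    oncotic_pressure_GB: float = 30.0
    baseline_afferent_resistance: float = 2.78e6
    feedback_gains: FeedbackGains = field(default_factory=FeedbackGains)
    systemic: SystemicParameters = field(default_factory=SystemicParameters)

    def __post_init__(self) -> None:
        _require(self.oncotic_pressure_GB >= 0.0, "oncotic pressure must be >= 0")
        _require(
            self.baseline_afferent_resistance > 0.0,
            "baseline afferent resistance must be > 0",
        )

    def with_gains(self, gains: FeedbackGains) -> "KidneyParameters":
        return replace(self, feedback_gains=gains)


@dataclass(frozen=True)
class FlowSet:
    """Per-nephron flows/fluxes at a solution (mL/s and mEq/s)."""

    # axial water flows
    q_HA: float
    q_AG: float
    q_GB: float  # glomerular filtration
    q_GE: float
    q_EV: float
    q_BP: float
    q_PN: float
    q_NK: float
    q_KD: float
    q_DU: float
    # water reabsorption to veins
    q_PV: float
    q_NV: float
    q_DV: float
    # advective sodium fluxes along the tubule
    j_BP: float
    j_PN: float
    j_NK: float
    j_KD: float
    j_DU: float
    # sodium reabsorption fluxes to veins
    j_PV: float
    j_KV: float
    j_DV: float


def aggregate_flow(per_nephron: float, systemic: SystemicParameters) -> float:
    """Convert a per-nephron mL/s (or mEq/s) value to whole-body mL/min."""
    return per_nephron * systemic.nephron_scale * 60.0


def per_nephron_flow(aggregate: float, systemic: SystemicParameters) -> float:
    """Convert a whole-body mL/min (or mEq/min) value to per-nephron mL/s."""
    return aggregate / systemic.nephron_scale / 60.0
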