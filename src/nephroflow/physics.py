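"""Constitutive relations: pressure-driven flow, Starling filtration,
reabsorption fractions, advection, and Poiseuille resistance.

Everything here is a pure scalar (numpy-broadcastable) function. Per-nephron
flows are in mL/s; the two empirical reabsorption relations take *aggregate*
inflows (mL/min water, mEq/min sodium), which is the unit system they were
fitted in — callers convert with :func:`nephroflow.params.aggregate_flow`.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    InvalidNodeError,
    InvalidParameterError,
    NodeId,
    ReabsorptionRules,
)

__all__ = [
    "hydraulic_flow",
    "starling_flow",
    "water_reabsorption_fraction",
    "sodium_reabsorption_fraction",
    "advective_flux",
    "poiseuille_resistance",
]

# Fractions are clamped to [0, 1): the empirical relations were fitted near
# baseline and would otherwise leave the physical range at extreme flows.
_FRACTION_CAP = 1.0 - 1e-12
_EXP_CLIP = 500.0  # exp argument guard


def hydraulic_flow(p_up: float, p_down: float, resistance: float) -> float:
    """Axial water flow (mL/s) through a vessel: (P_up - P_down) / R.

    Positive along the network's arrow direction; antisymmetric under a
    pressure swap.
    """
    if resistance <= 0.0:
        raise InvalidParameterError("hydraulic resistance must be positive")
    return (p_up - p_down) / resistance


def starling_flow(
    p_G: float, p_B: float, oncotic: float, resistance: float
) -> float:
    """Glomerular filtration (mL/s): (P_G - P_B - pi) / R_GB.

    The oncotic pressure of unfiltered plasma proteins opposes filtration with
    a reflection coefficient of unity; with ``oncotic=0`` this reduces to
    :func:`hydraulic_flow`.
    """
    if resistance <= 0.0:
        raise InvalidParameterError("filtration resistance must be positive")
    if oncotic < 0.0:
        raise InvalidParameterError("oncotic pressure must be nonnegative")
    return (p_G - p_B - oncotic) / resistance


def water_reabsorption_fraction(
    node: NodeId,
    axial_inflow_ml_min: float,
    rules: ReabsorptionRules | None = None,
) -> float:
    """Fraction of the incoming axial water flow reabsorbed at a tubular node.

    Parameters
    ----------
    node
        One of P, N, K, D.
    axial_inflow_ml_min
        Aggregate (whole-body) water inflow into the node, mL/min.

    The proximal tubule reabsorbs a constant 0.75 (glomerulotubular balance);
    the distal tubule a constant 0.95 (fixed ADH); the thick ascending limb is
    water-impermeable (0); the thin descending limb follows the inverse-linear
    relation ``0.65 - 0.01 Q`` clamped to [0, 1).
    """
    rules = rules or ReabsorptionRules()
    if axial_inflow_ml_min < 0.0:
        raise InvalidParameterError("axial inflow must be nonnegative")
    node = NodeId(node)
    if node is NodeId.P:
        return rules.water_fraction_P
    if node is NodeId.D:
        return rules.water_fraction_D
    if node is NodeId.K:
        return 0.0
    if node is NodeId.N:
        raw = rules.descending_intercept - rules.descending_slope * axial_inflow_ml_min
        return float(min(max(raw, 0.0), _FRACTION_CAP))
    raise InvalidNodeError(f"node {node} has no water reabsorption fraction")


def sodium_reabsorption_fraction(
    node: NodeId,
    sodium_inflow_meq_min: float,
    rules: ReabsorptionRules | None = None,
) -> float:
    """Fraction of the incoming sodium flux reabsorbed at a tubular node.

    Parameters
    ----------
    node
        One of P, N, K, D.
    sodium_inflow_meq_min
        Aggregate sodium inflow into the node, mEq/min.

    P reabsorbs 0.75 (one-to-one with water); the thin descending limb is
    sodium-impermeable (0); the thick ascending limb a constant 0.80; the
    distal tubule follows the aldosterone-modulated inverse sigmoid
    ``0.2268 / (1 + exp(7 J - 7.7)) + 0.7316``, strictly decreasing in the
    delivered load.
    """
    rules = rules or ReabsorptionRules()
    if sodium_inflow_meq_min < 0.0:
        raise InvalidParameterError("sodium inflow must be nonnegative")
    node = NodeId(node)
    if node is NodeId.P:
        return rules.sodium_fraction_P
    if node is NodeId.N:
        return 0.0
    if node is NodeId.K:
        return rules.sodium_fraction_K
    if node is NodeId.D:
        arg = rules.distal_rate * sodium_inflow_meq_min - rules.distal_shift
        arg = min(max(arg, -_EXP_CLIP), _EXP_CLIP)
        raw = rules.distal_amplitude / (1.0 + math.exp(arg)) + rules.distal_floor
        return float(min(max(raw, 0.0), _FRACTION_CAP))
    raise InvalidNodeError(f"node {node} has no sodium reabsorption fraction")


def advective_flux(flow: float, concentration: float) -> float:
    """Advective sodium flux (mEq/s): bulk flow times upstream concentration."""
    if concentration < 0.0:
        raise InvalidParameterError("concentration must be nonnegative")
    return flow * concentration


def poiseuille_resistance(viscosity: float, length: float, radius: float) -> float:
    """Laminar-flow resistance of a cylindrical vessel: 8*eta*l / (pi*r^4).

    Homogeneous of degree -3 under uniform geometric scaling of both length
    and radius, so a uniform shrink by 6**(-1/3) ~ 0.55 multiplies the
    resistance by six.
    """
    if viscosity <= 0.0 or length <= 0.0 or radius <= 0.0:
        raise InvalidParameterError("viscosity, length and radius must be > 0")
    return 8.0 * viscosity * length / (np.pi * radius**4)
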