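"""Renal autoregulation: the three mechanisms that modulate afferent
arteriole resistance.

Tubuloglomerular feedback (TGF) senses distal sodium concentration;
the descending myogenic mechanism senses pre-afferent pressure above a
67 mmHg threshold; the ascending myogenic mechanism senses the afferent
resistances themselves (and so composes after TGF and the descending
response). All three act on the same actuator — the afferent arteriole —
additively on top of the feedback-free baseline resistance::

    R_AG = R_b + R_TGF + R_MD + R_MA

Each mechanism's output is multiplied by a dimensionless gain: ones for a
healthy subject, zeros for an open loop.

The TGF and ascending relations are expressed in a normalized resistance unit
(``RESISTANCE_UNIT`` = 1e7 mmHg*s/mL, in which the filtration resistance is
exactly 1); their outputs are rescaled to absolute mmHg*s/mL here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import RESISTANCE_UNIT, FeedbackGains, InvalidParameterError

__all__ = [
    "FeedbackState",
    "tgf_resistance",
    "descending_myogenic_resistance",
    "ascending_myogenic_resistance",
    "afferent_resistance",
    "MYOGENIC_PRESSURE_THRESHOLD",
]

#: Pre-afferent pressure (mmHg) above which the descending myogenic
#: mechanism engages.
MYOGENIC_PRESSURE_THRESHOLD = 67.0

_TGF_AMPLITUDE = 0.1505  # in RESISTANCE_UNIT
_TGF_SHIFT = 4.8
_TGF_RATE = 40.0  # per (mEq/mL); midpoint at C_D = 0.12 mEq/mL
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class FeedbackState:
    """Resolved feedback contributions and the resulting total, mmHg*s/mL."""

    r_tgf: float
    r_myogenic_descending: float
    r_myogenic_ascending: float
    r_afferent_total: float

    def __post_init__(self) -> None:
        for name in ("r_tgf", "r_myogenic_descending", "r_myogenic_ascending"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be nonnegative")


def tgf_resistance(c_D: float, gain: float = 1.0) -> float:
    """TGF contribution (mmHg*s/mL) as a sigmoid of distal sodium.

    ``gain * U * 0.1505 / (1 + exp(4.8 - 40 c_D))`` with ``c_D`` in mEq/mL:
    strictly increasing, midpoint at 0.12 mEq/mL, saturating at 0.1505 U.
    """
    if c_D < 0.0:
        raise InvalidParameterError("distal sodium concentration must be >= 0")
    if gain < 0.0:
        raise InvalidParameterError("gain must be nonnegative")
    arg = _TGF_SHIFT - _TGF_RATE * c_D
    arg = min(max(arg, -_EXP_CLIP), _EXP_CLIP)
    return gain * RESISTANCE_UNIT * _TGF_AMPLITUDE / (1.0 + math.exp(arg))


def descending_myogenic_resistance(
    p_A: float,
    r_b: float,
    r_GE: float,
    r_tgf: float,
    gain: float = 1.0,
) -> float:
    """Descending myogenic contribution (mmHg*s/mL).

    ``gain * 0.5 (R_b + R_GE + R_TGF) (P_A/67 - 1) H(P_A - 67)``: zero below
    the 67 mmHg threshold, then linear in pre-afferent pressure. The Heaviside
    evaluates to 1 at exactly 67, where the linear factor vanishes, so the
    response is continuous. ``r_tgf`` is the gain-scaled TGF contribution.
    """
    if min(r_b, r_GE, r_tgf) < 0.0:
        raise InvalidParameterError("resistances must be nonnegative")
    if gain < 0.0:
        raise InvalidParameterError("gain must be nonnegative")
    heaviside = 1.0 if p_A >= MYOGENIC_PRESSURE_THRESHOLD else 0.0
    slope = p_A / MYOGENIC_PRESSURE_THRESHOLD - 1.0
    return gain * 0.5 * (r_b + r_GE + r_tgf) * slope * heaviside


def ascending_myogenic_resistance(
    r_b: float,
    r_md: float,
    r_GE: float,
    gain: float = 1.0,
) -> float:
    """Ascending myogenic contribution (mmHg*s/mL).

    ``gain * U * 0.5 (R_b + R_MD) / R_GE``; the resistance ratio is
    dimensionless and the normalized unit restores the absolute scale.
    ``r_md`` is the gain-scaled descending contribution, so this mechanism
    composes after the other two.
    """
    if r_GE <= 0.0:
        raise InvalidParameterError("efferent resistance must be positive")
    if min(r_b, r_md) < 0.0:
        raise InvalidParameterError("resistances must be nonnegative")
    if gain < 0.0:
        raise InvalidParameterError("gain must be nonnegative")
    return gain * RESISTANCE_UNIT * 0.5 * (r_b + r_md) / r_GE


def afferent_resistance(
    r_b: float,
    p_A: float,
    c_D: float,
    r_GE: float,
    gains: FeedbackGains,
) -> FeedbackState:
    """Total afferent arteriole resistance with all feedback components.

    Composition order is fixed — TGF, then descending myogenic (which
    consumes the gain-scaled TGF term), then ascending myogenic (which
    consumes the gain-scaled descending term) — and the three contributions
    add on top of the baseline. With all gains zero the total collapses to
    ``r_b``.
    """
    if r_b <= 0.0:
        raise InvalidParameterError("baseline afferent resistance must be > 0")
    r_tgf = tgf_resistance(c_D, gains.tgf)
    r_md = descending_myogenic_resistance(
        p_A, r_b, r_GE, r_tgf, gains.myogenic_descending
    )
    r_ma = ascending_myogenic_resistance(r_b, r_md, r_GE, gains.myogenic_ascending)
    return FeedbackState(
        r_tgf=r_tgf,
        r_myogenic_descending=r_md,
        r_myogenic_ascending=r_ma,
        r_afferent_total=r_b + r_tgf + r_md + r_ma,
    )
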