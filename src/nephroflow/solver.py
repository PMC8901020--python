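"""Steady-state solve of the node-wise water and sodium continuity equations.

Unknowns (12, fixed order)
--------------------------
pressures at the interior nodes ``A, G, B, P, N, K, D, E`` (mmHg), then
sodium concentrations at the tubular nodes ``P, N, K, D`` (mEq/mL).
Concentrations at Bowman's space and the veins are fixed by the boundary
(free filtration), so they carry no unknown; the veins are a pressure
boundary, so reabsorbed flows merge into them without a continuity equation.

At each interior node the water residual is inflow minus outflow (with the
afferent resistance evaluated from the *current* iterate through the feedback
relations), and at each tubular node the sodium residual is advective inflow
minus reabsorbed and advected outflow. The resulting 12-dimensional nonlinear
system is solved with a damped Newton method: central finite-difference
Jacobian, backtracking line search on the scaled residual norm, unknowns
scaled by 100 mmHg / 0.14 mEq/mL and residuals by typical per-nephron flow
magnitudes to condition the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import physics
from .feedback import FeedbackState, afferent_resistance
from .params import (
    BoundaryConditions,
    FlowSet,
    InvalidParameterError,
    KidneyParameters,
    NodeId,
    aggregate_flow,
)

__all__ = [
    "UNKNOWN_LAYOUT",
    "SolverOptions",
    "SteadyStateSolution",
    "SolverError",
    "assemble_residuals",
    "default_initial_guess",
    "solve_steady_state",
    "summarize",
]

#: Order of the unknown vector: (kind, node).
UNKNOWN_LAYOUT: tuple[tuple[str, NodeId], ...] = (
    ("pressure", NodeId.A),
    ("pressure", NodeId.G),
    ("pressure", NodeId.B),
    ("pressure", NodeId.P),
    ("pressure", NodeId.N),
    ("pressure", NodeId.K),
    ("pressure", NodeId.D),
    ("pressure", NodeId.E),
    ("sodium", NodeId.P),
    ("sodium", NodeId.N),
    ("sodium", NodeId.K),
    ("sodium", NodeId.D),
)

N_UNKNOWNS = len(UNKNOWN_LAYOUT)

# internal scaling of unknowns (mmHg / mEq/mL) and residuals (mL/s / mEq/s)
_X_SCALE = np.array([100.0] * 8 + [0.14] * 4)
_F_SCALE = np.array([1e-6] * 8 + [1.4e-7] * 4)


class SolverError(RuntimeError):
    """The Newton iteration failed in a way that has no usable result."""


@dataclass(frozen=True)
class SolverOptions:
    """Newton iteration controls."""

    tolerance: float = 1e-10  # on the scaled residual norm
    max_iterations: int = 100
    fd_step: float = 1e-6  # relative central-difference step
    max_backtracks: int = 40

    def __post_init__(self) -> None:
        if self.tolerance <= 0.0:
            raise InvalidParameterError("tolerance must be positive")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")


def _flows(
    x: np.ndarray, params: KidneyParameters, bc: BoundaryConditions
) -> tuple[FlowSet, FeedbackState, float, float]:
    """Evaluate all edge flows/fluxes and the feedback state at an iterate.

    Returns the flow set, the feedback state, and the two state-dependent
    reabsorption fractions (descending-limb water, distal sodium).
    """
    p_A, p_G, p_B, p_P, p_N, p_K, p_D, p_E = x[:8]
    c_P, c_N, c_K, c_D = x[8:]
    R = params.resistances
    sysm = params.systemic
    rules = params.reabsorption

    # transient negative concentrations can appear mid-iteration; the feedback
    # relations are defined on [0, inf), so evaluate at the clamped value
    fb = afferent_resistance(
        params.baseline_afferent_resistance,
        p_A,
        max(c_D, 0.0),
        R.r_GE,
        params.feedback_gains,
    )

    q_HA = physics.hydraulic_flow(bc.map_pressure, p_A, R.r_HA)
    q_AG = physics.hydraulic_flow(p_A, p_G, fb.r_afferent_total)
    q_GB = physics.starling_flow(p_G, p_B, params.oncotic_pressure_GB, R.r_GB)
    q_GE = physics.hydraulic_flow(p_G, p_E, R.r_GE)
    q_EV = physics.hydraulic_flow(p_E, bc.venous_pressure, R.r_EV)
    q_BP = physics.hydraulic_flow(p_B, p_P, R.r_BP)
    q_PN = physics.hydraulic_flow(p_P, p_N, R.r_PN)
    q_NK = physics.hydraulic_flow(p_N, p_K, R.r_NK)
    q_KD = physics.hydraulic_flow(p_K, p_D, R.r_KD)
    q_DU = physics.hydraulic_flow(p_D, bc.ureter_pressure, R.r_DU)

    # empirical fractions take aggregate inflows; guard against transient
    # negative flows mid-iteration by clamping the argument at zero
    r_N = physics.water_reabsorption_fraction(
        NodeId.N, max(aggregate_flow(q_PN, sysm), 0.0), rules
    )
    j_KD = physics.advective_flux(q_KD, max(c_K, 0.0))
    r_D_na = physics.sodium_reabsorption_fraction(
        NodeId.D, max(aggregate_flow(j_KD, sysm), 0.0), rules
    )

    j_BP = physics.advective_flux(q_BP, bc.venous_sodium)
    j_PN = physics.advective_flux(q_PN, max(c_P, 0.0))
    j_NK = physics.advective_flux(q_NK, max(c_N, 0.0))
    j_DU = physics.advective_flux(q_DU, max(c_D, 0.0))

    flows = FlowSet(
        q_HA=q_HA, q_AG=q_AG, q_GB=q_GB, q_GE=q_GE, q_EV=q_EV,
        q_BP=q_BP, q_PN=q_PN, q_NK=q_NK, q_KD=q_KD, q_DU=q_DU,
        q_PV=rules.water_fraction_P * q_BP,
        q_NV=r_N * q_PN,
        q_DV=rules.water_fraction_D * q_KD,
        j_BP=j_BP, j_PN=j_PN, j_NK=j_NK, j_KD=j_KD, j_DU=j_DU,
        j_PV=rules.sodium_fraction_P * j_BP,
        j_KV=rules.sodium_fraction_K * j_NK,
        j_DV=r_D_na * j_KD,
    )
    return flows, fb, r_N, r_D_na


def assemble_residuals(
    x: Sequence[float], params: KidneyParameters, bc: BoundaryConditions
) -> np.ndarray:
    """Mass-conservation residual vector (length 12) at an unknown vector.

    Water continuity at A, G, B, P, N, K, D, E followed by sodium continuity
    at P, N, K, D; smooth in ``x`` except at the myogenic pressure threshold.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_UNKNOWNS,):
        raise InvalidParameterError(
            f"unknown vector must have length {N_UNKNOWNS}, got {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("unknown vector contains non-finite entries")

    fl, _, r_N, r_D_na = _flows(x, params, bc)
    rules = params.reabsorption
    c_P, c_N, c_K, c_D = x[8:]

    F = np.empty(N_UNKNOWNS)
    # water
    F[0] = fl.q_HA - fl.q_AG                                   # node A
    F[1] = fl.q_AG - fl.q_GB - fl.q_GE                         # node G
    F[2] = fl.q_GB - fl.q_BP                                   # node B
    F[3] = (1.0 - rules.water_fraction_P) * fl.q_BP - fl.q_PN  # node P
    F[4] = (1.0 - r_N) * fl.q_PN - fl.q_NK                     # node N
    F[5] = fl.q_NK - fl.q_KD                                   # node K (impermeable)
    F[6] = (1.0 - rules.water_fraction_D) * fl.q_KD - fl.q_DU  # node D
    F[7] = fl.q_GE - fl.q_EV                                   # node E
    # sodium
    F[8] = (1.0 - rules.sodium_fraction_P) * fl.j_BP - fl.q_PN * c_P   # node P
    F[9] = fl.q_PN * c_P - fl.q_NK * c_N                               # node N
    F[10] = (1.0 - rules.sodium_fraction_K) * fl.j_NK - fl.q_KD * c_K  # node K
    F[11] = (1.0 - r_D_na) * fl.j_KD - fl.q_DU * c_D                   # node D
    return F


def default_initial_guess(
    params: KidneyParameters, bc: BoundaryConditions
) -> np.ndarray:
    """Linear pressure ramps along each chain; concentrations forward-propagated.

    Tubular concentrations start from the venous value pushed through the
    baseline reabsorption fractions (proximal iso-osmotic, descending-limb
    concentration, ascending-limb dilution, distal concentration): starting
    TGF on the correct branch of its sigmoid keeps the Newton steps well
    inside the region where the local linear model is valid.
    """
    m = bc.map_pressure
    v = bc.venous_pressure
    u = bc.ureter_pressure
    rules = params.reabsorption
    # blood chain H -> A -> G -> E -> V; filtrate G - oncotic - NFP -> ... -> U
    p_A = m - (m - v) * 0.15
    p_G = m - (m - v) * 0.5
    p_B = max(p_G - params.oncotic_pressure_GB - 10.0, u + 1.0)
    tub = np.linspace(p_B, u, 6)  # B, P, N, K, D, U
    p_E = v + (p_G - v) * 0.25
    # concentration cascade at baseline fractions (r_N ~ 0.35, r_D from its
    # own sigmoid evaluated at the implied load)
    c_P = bc.venous_sodium
    r_N0 = 1.0 - (1.0 - rules.descending_intercept) - 0.3 * rules.descending_slope / 0.01
    r_N0 = min(max(r_N0, 0.0), 0.95)
    c_N = c_P / (1.0 - r_N0)
    c_K = (1.0 - rules.sodium_fraction_K) * c_N
    c_D = 4.0 * (1.0 - rules.distal_floor) * c_K
    x0 = np.array(
        [p_A, p_G, p_B, tub[1], tub[2], tub[3], tub[4], p_E, c_P, c_N, c_K, c_D]
    )
    return x0


@dataclass(frozen=True)
class SteadyStateSolution:
    """Converged (or diagnosed) steady state with whole-body outputs.

    Attributes
    ----------
    pressures, sodium : dict
        Node -> mmHg and node -> mEq/mL (tubular nodes plus the boundary
        values at B and V).
    flows : FlowSet
        Per-nephron flows (mL/s) and sodium fluxes (mEq/s).
    feedback : FeedbackState
        Afferent-resistance decomposition at the solution.
    gfr, rpf, urine_flow : float
        Whole-body outputs in mL/min.
    urine_sodium : float or None
        Urinary sodium concentration (mEq/mL); None when urine flow is zero.
    """

    pressures: dict[NodeId, float]
    sodium: dict[NodeId, float]
    flows: FlowSet
    feedback: FeedbackState
    converged: bool
    residual_norm: float
    iterations: int
    gfr: float
    rpf: float
    urine_flow: float
    urine_sodium: float | None
    water_reabsorption_N: float
    sodium_reabsorption_D: float
    params: KidneyParameters = field(repr=False)
    boundary: BoundaryConditions = field(repr=False)

    @property
    def x(self) -> np.ndarray:
        """The raw unknown vector in :data:`UNKNOWN_LAYOUT` order."""
        return np.array(
            [self.pressures[n] for _, n in UNKNOWN_LAYOUT[:8]]
            + [self.sodium[n] for _, n in UNKNOWN_LAYOUT[8:]]
        )

    def summary(self) -> str:
        """Human-readable report of the solved state."""
        lines = [
            "Steady-state kidney solution",
            "============================",
            f"converged: {self.converged}  (residual {self.residual_norm:.3e}, "
            f"{self.iterations} Newton iterations)",
            f"MAP {self.boundary.map_pressure:.1f} mmHg | gains "
            f"(TGF {self.params.feedback_gains.tgf:g}, "
            f"MD {self.params.feedback_gains.myogenic_descending:g}, "
            f"MA {self.params.feedback_gains.myogenic_ascending:g})",
            "",
            f"GFR        {self.gfr:8.1f} mL/min",
            f"RPF        {self.rpf:8.1f} mL/min",
            f"urine flow {self.urine_flow:8.2f} mL/min",
        ]
        if self.urine_sodium is not None:
            lines.append(f"urine [Na] {self.urine_sodium * 1000:8.1f} mEq/L")
        lines.append("")
        lines.append("node   P (mmHg)   C_Na (mEq/L)")
        for node in (NodeId.A, NodeId.G, NodeId.B, NodeId.P, NodeId.N,
                     NodeId.K, NodeId.D, NodeId.E):
            c = self.sodium.get(node)
            cs = f"{c * 1000:10.1f}" if c is not None else "         -"
            lines.append(f"  {node.value}   {self.pressures[node]:9.3f} {cs}")
        fb = self.feedback
        lines.append("")
        lines.append(
            "afferent resistance (mmHg*s/mL): total "
            f"{fb.r_afferent_total:.4g} = base "
            f"{self.params.baseline_afferent_resistance:.4g}"
            f" + TGF {fb.r_tgf:.4g} + MD {fb.r_myogenic_descending:.4g}"
            f" + MA {fb.r_myogenic_ascending:.4g}"
        )
        return "\n".join(lines)


def summarize(
    x: np.ndarray,
    params: KidneyParameters,
    bc: BoundaryConditions,
    *,
    converged: bool,
    residual_norm: float,
    iterations: int,
) -> SteadyStateSolution:
    """Package an unknown vector into a solution with whole-body outputs.

    Per-nephron flows are scaled by the nephron count and converted to
    mL/min; urinary sodium concentration is the urinary sodium flux divided
    by urine flow (undefined, reported as None, at zero urine flow).
    """
    fl, fb, r_N, r_D_na = _flows(x, params, bc)
    sysm = params.systemic
    pressures = {node: float(x[i]) for i, (k, node) in enumerate(UNKNOWN_LAYOUT) if k == "pressure"}
    pressures[NodeId.H] = bc.map_pressure
    pressures[NodeId.V] = bc.venous_pressure
    pressures[NodeId.U] = bc.ureter_pressure
    sodium = {node: float(x[i]) for i, (k, node) in enumerate(UNKNOWN_LAYOUT) if k == "sodium"}
    sodium[NodeId.B] = bc.venous_sodium
    sodium[NodeId.V] = bc.venous_sodium

    urine_flow = aggregate_flow(fl.q_DU, sysm)
    urine_na = None
    if urine_flow > 0.0:
        urine_na = fl.j_DU / fl.q_DU  # concentration is scale-free
    return SteadyStateSolution(
        pressures=pressures,
        sodium=sodium,
        flows=fl,
        feedback=fb,
        converged=converged,
        residual_norm=residual_norm,
        iterations=iterations,
        gfr=aggregate_flow(fl.q_GB, sysm),
        rpf=aggregate_flow(fl.q_HA, sysm),
        urine_flow=urine_flow,
        urine_sodium=urine_na,
        water_reabsorption_N=r_N,
        sodium_reabsorption_D=r_D_na,
        params=params,
        boundary=bc,
    )


def _jacobian(
    x: np.ndarray,
    params: KidneyParameters,
    bc: BoundaryConditions,
    fd_step: float,
) -> np.ndarray:
    J = np.empty((N_UNKNOWNS, N_UNKNOWNS))
    for j in range(N_UNKNOWNS):
        h = fd_step * _X_SCALE[j]
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        # derivative of the scaled residual w.r.t. the scaled unknown x_j/_X_SCALE[j]
        J[:, j] = (
            assemble_residuals(xp, params, bc) - assemble_residuals(xm, params, bc)
        ) * (_X_SCALE[j] / (2.0 * h)) / _F_SCALE
    return J


def solve_steady_state(
    params: KidneyParameters,
    bc: BoundaryConditions | None = None,
    opts: SolverOptions | None = None,
    x0: np.ndarray | None = None,
    log: list[float] | None = None,
) -> SteadyStateSolution:
    """Damped Newton solve of the 12-equation continuity system.

    Parameters
    ----------
    x0
        Optional warm start (e.g. the previous solution of a MAP sweep);
        defaults to :func:`default_initial_guess`.
    log
        Optional list that receives the scaled residual norm per iteration.

    Non-convergence is reported in the returned solution's ``converged`` flag
    and diagnostics, never silently; a singular Jacobian raises
    :class:`SolverError`.
    """
    bc = bc or BoundaryConditions()
    opts = opts or SolverOptions()
    x = np.array(x0, dtype=float) if x0 is not None else default_initial_guess(params, bc)

    norm = np.inf
    it = 0
    for it in range(opts.max_iterations):
        F = assemble_residuals(x, params, bc) / _F_SCALE
        norm = float(np.linalg.norm(F))
        if log is not None:
            log.append(norm)
        if norm < opts.tolerance:
            return summarize(
                x, params, bc, converged=True, residual_norm=norm, iterations=it
            )
        J = _jacobian(x, params, bc, opts.fd_step)
        try:
            dx = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as exc:
            raise SolverError(
                f"singular Jacobian at iteration {it} (residual {norm:.3e})"
            ) from exc
        # backtracking line search on the scaled residual norm
        lam = 1.0
        for _ in range(opts.max_backtracks):
            x_new = x + lam * dx * _X_SCALE
            new_norm = float(
                np.linalg.norm(assemble_residuals(x_new, params, bc) / _F_SCALE)
            )
            if new_norm < norm * (1.0 - 1e-4 * lam):
                break
            lam *= 0.5
        x = x + lam * dx * _X_SCALE

    F = assemble_residuals(x, params, bc) / _F_SCALE
    norm = float(np.linalg.norm(F))
    return summarize(
        x,
        params,
        bc,
        converged=norm < opts.tolerance,
        residual_norm=norm,
        iterations=opts.max_iterations,
    )
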