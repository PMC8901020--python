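"""Newton solve of the 12-equation continuity system: baseline values,
mass conservation, the two-stage linear oracle, and failure modes."""

from dataclasses import replace

import numpy as np
import pytest

from nephroflow import (
    BoundaryConditions,
    FeedbackGains,
    InvalidParameterError,
    NodeId,
    ReabsorptionRules,
    SolverOptions,
    assemble_residuals,
    solve_steady_state,
)
from nephroflow.solver import (
    N_UNKNOWNS,
    UNKNOWN_LAYOUT,
    default_initial_guess,
)


class TestBaselineSolution:
    def test_converges_to_tolerance(self, baseline_solution):
        sol = baseline_solution
        assert sol.converged
        assert sol.residual_norm < 1e-10
        assert sol.iterations < 30

    def test_whole_body_outputs(self, baseline_solution):
        sol = baseline_solution
        assert sol.gfr == pytest.approx(120.0, rel=1e-9)
        assert sol.rpf == pytest.approx(605.0, rel=1e-9)
        # 25% of GFR enters the loop, 35% of that is reabsorbed in the
        # descending limb, 95% of the remainder in the distal tubule
        assert sol.urine_flow == pytest.approx(0.05 * 0.65 * 30.0, rel=1e-9)

    def test_tubular_concentration_cascade(self, baseline_solution):
        na = baseline_solution.sodium
        assert na[NodeId.P] == pytest.approx(0.14, rel=1e-9)
        assert na[NodeId.N] == pytest.approx(0.14 / 0.65, rel=1e-9)
        assert na[NodeId.K] == pytest.approx(0.2 * 0.14 / 0.65, rel=1e-9)
        # distal concentration from the sigmoid at 0.84 mEq/min delivery
        assert na[NodeId.D] == pytest.approx(0.06308494974940498, rel=1e-8)
        assert baseline_solution.urine_sodium == pytest.approx(
            na[NodeId.D], rel=1e-12
        )

    def test_reproduces_fixture_pressures(self, baseline_fixture, baseline_solution):
        # the calibrated model's solve is a fixed point of the prescribed profile
        for node, p_ref in baseline_fixture.pressures.items():
            assert baseline_solution.pressures[node] == pytest.approx(
                p_ref, abs=1e-6
            ), node

    def test_summary_mentions_key_outputs(self, baseline_solution):
        text = baseline_solution.summary()
        assert "GFR" in text and "120.0" in text
        assert "converged: True" in text
        assert "afferent resistance" in text


class TestConservation:
    def _check(self, sol):
        fl = sol.flows
        water_in = fl.q_HA
        water_out = fl.q_EV + fl.q_PV + fl.q_NV + fl.q_DV + fl.q_DU
        assert water_out == pytest.approx(water_in, rel=1e-8)
        sodium_in = fl.j_BP
        sodium_out = fl.j_PV + fl.j_KV + fl.j_DV + fl.j_DU
        assert sodium_out == pytest.approx(sodium_in, rel=1e-8)

    def test_baseline(self, baseline_solution):
        self._check(baseline_solution)

    def test_every_sweep_point(self, closed_loop_sweep):
        for sol in closed_loop_sweep.solutions:
            assert sol.converged
            self._check(sol)


class TestManufacturedState:
    def test_fixture_state_is_near_zero_residual(
        self, baseline_fixture, baseline_model
    ):
        """The prescribed pressures + calibration concentrations solve the
        system by construction (the fixture is feedback-consistent)."""
        from nephroflow import resistances_from_continuity

        fx = baseline_fixture
        calib = resistances_from_continuity(
            fx.pressures,
            fx.constants["gfr_target_ml_min"],
            fx.systemic_parameters(),
            r_GB=fx.constants["filtration_resistance"],
            venous_sodium=fx.constants["venous_sodium_meq_per_ml"],
        )
        x = np.array(
            [fx.pressures[n] for _, n in UNKNOWN_LAYOUT[:8]]
            + [calib.sodium[n] for _, n in UNKNOWN_LAYOUT[8:]]
        )
        F = assemble_residuals(
            x, baseline_model.params, baseline_model.boundary
        )
        # per-nephron flows are O(1e-6) mL/s; residuals are exact to rounding
        assert np.max(np.abs(F)) < 1e-18


#: Frozen-fraction rules: descending-limb water fraction constant at its
#: baseline 0.35, distal sodium fraction constant at its baseline value.
_FROZEN_RULES = ReabsorptionRules(
    descending_intercept=0.35,
    descending_slope=0.0,
    distal_amplitude=0.0,
    distal_floor=0.9267763976122978,
)


class TestLinearOracle:
    """With gains zero and reabsorption fractions frozen, the water equations
    are affine in the pressures and, given the flows, the sodium equations are
    linear in the concentrations. The Newton solution must match this direct
    two-stage solve."""

    @pytest.fixture()
    def frozen_params(self, baseline_model):
        return replace(
            baseline_model.params,
            reabsorption=_FROZEN_RULES,
            feedback_gains=FeedbackGains.open_loop(),
        )

    def _oracle(self, params, bc):
        # stage 1: pressures from the affine water block (concentrations
        # do not enter the water residuals)
        c_fill = np.array([0.14, 0.2, 0.05, 0.06])

        def water(p):
            return assemble_residuals(np.concatenate([p, c_fill]), params, bc)[:8]

        b = water(np.zeros(8))
        A = np.column_stack([water(e) - b for e in np.eye(8)])
        p = np.linalg.solve(A, -b)

        # stage 2: concentrations closed-form from the solved flows
        R = params.resistances
        rules = params.reabsorption
        p_A, p_G, p_B, p_P, p_N, p_K, p_D, p_E = p
        q_BP = (p_B - p_P) / R.r_BP
        q_PN = (p_P - p_N) / R.r_PN
        q_NK = (p_N - p_K) / R.r_NK
        q_KD = (p_K - p_D) / R.r_KD
        q_DU = (p_D - bc.ureter_pressure) / R.r_DU
        c_P = (1 - rules.sodium_fraction_P) * q_BP * bc.venous_sodium / q_PN
        c_N = q_PN * c_P / q_NK
        c_K = (1 - rules.sodium_fraction_K) * q_NK * c_N / q_KD
        c_D = (1 - rules.distal_floor) * q_KD * c_K / q_DU
        return np.concatenate([p, [c_P, c_N, c_K, c_D]])

    def test_water_residuals_affine(self, frozen_params):
        """Affinity check on the water block: F(x) - F(0) is exactly linear."""
        bc = BoundaryConditions()
        rng = np.random.default_rng(7)
        c_fill = np.array([0.14, 0.2, 0.05, 0.06])

        def water(p):
            return assemble_residuals(
                np.concatenate([p, c_fill]), frozen_params, bc
            )[:8]

        b = water(np.zeros(8))
        A = np.column_stack([water(e) - b for e in np.eye(8)])
        for _ in range(5):
            p = rng.uniform(0.0, 120.0, size=8)
            np.testing.assert_allclose(water(p), A @ p + b, rtol=0, atol=1e-18)

    # converge well past the default tolerance so the comparison probes the
    # fixed point itself, not the stopping criterion
    _TIGHT = SolverOptions(tolerance=1e-13)

    @pytest.mark.parametrize("map_pressure", [60.0, 90.0, 150.0])
    def test_newton_matches_oracle(self, frozen_params, map_pressure):
        bc = BoundaryConditions(map_pressure=map_pressure)
        x_direct = self._oracle(frozen_params, bc)
        sol = solve_steady_state(frozen_params, bc, self._TIGHT)
        assert sol.converged
        np.testing.assert_allclose(sol.x, x_direct, rtol=1e-10)


class TestRobustness:
    def test_initial_guess_invariance(self, baseline_model):
        params, bc = baseline_model.params, baseline_model.boundary
        ref = solve_steady_state(params, bc)
        x0 = default_initial_guess(params, bc)
        rng = np.random.default_rng(42)
        for _ in range(3):
            perturbed = x0 * rng.uniform(0.8, 1.2, size=x0.shape)
            sol = solve_steady_state(params, bc, x0=perturbed)
            assert sol.converged
            np.testing.assert_allclose(sol.x, ref.x, rtol=1e-6, atol=1e-9)

    def test_wrong_length_unknown_vector(self, baseline_model):
        with pytest.raises(InvalidParameterError):
            assemble_residuals(
                np.zeros(5), baseline_model.params, baseline_model.boundary
            )

    def test_non_finite_unknowns_rejected(self, baseline_model):
        x = np.full(N_UNKNOWNS, np.nan)
        with pytest.raises(InvalidParameterError):
            assemble_residuals(x, baseline_model.params, baseline_model.boundary)

    def test_non_convergence_is_flagged_not_silent(self, baseline_model):
        opts = SolverOptions(max_iterations=1)
        sol = solve_steady_state(
            baseline_model.params, baseline_model.boundary, opts
        )
        assert not sol.converged
        assert sol.residual_norm > opts.tolerance

    def test_iteration_log(self, baseline_model):
        log: list[float] = []
        sol = solve_steady_state(
            baseline_model.params, baseline_model.boundary, log=log
        )
        assert sol.converged
        assert len(log) == sol.iterations + 1
        assert log[-1] < 1e-10

    def test_options_validation(self):
        with pytest.raises(InvalidParameterError):
            SolverOptions(tolerance=0.0)
        with pytest.raises(InvalidParameterError):
            SolverOptions(max_iterations=0)
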