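"""MAP sweeps, scenarios, sensitivity grids, interpolation, RMSE, ablation."""

import numpy as np
import pandas as pd
import pytest

from nephroflow import (
    BASELINE_SCENARIO,
    SEVERE_HYPERTENSION,
    FeedbackGains,
    InvalidParameterError,
    ScenarioSpec,
    SweepSpec,
    apply_scenario,
    interpolate_curve,
    map_sweep,
    rmse_against_observations,
)
from nephroflow.experiments import validate_ablation


class TestSweepSpec:
    def test_default_grid(self):
        grid = SweepSpec().map_values
        assert len(grid) == 15
        assert grid[0] == 54.0 and grid[-1] == 180.0
        np.testing.assert_allclose(np.diff(grid), 9.0)

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            SweepSpec(map_min=100.0, map_max=90.0)
        with pytest.raises(InvalidParameterError):
            SweepSpec(step=0.0)

    def test_ablation_rejected_in_spec(self):
        with pytest.raises(InvalidParameterError):
            SweepSpec(gains=FeedbackGains(tgf=0.0, myogenic_ascending=1.0))


class TestAblation:
    def test_ascending_without_tgf_rejected(self):
        with pytest.raises(InvalidParameterError):
            validate_ablation(FeedbackGains(tgf=0.0, myogenic_ascending=0.5))

    def test_valid_combinations_pass(self):
        for g in (
            FeedbackGains(),
            FeedbackGains.open_loop(),
            FeedbackGains(tgf=1.0, myogenic_descending=0.0, myogenic_ascending=0.0),
            FeedbackGains(tgf=0.0, myogenic_descending=1.0, myogenic_ascending=0.0),
        ):
            assert validate_ablation(g) is g


class TestMapSweep:
    def test_closed_loop_rows(self, closed_loop_sweep):
        t = closed_loop_sweep.table
        assert len(t) == 15
        assert closed_loop_sweep.all_converged
        at_90 = t.loc[t["map_mmHg"] == 90.0, "gfr_ml_min"].iloc[0]
        assert at_90 == pytest.approx(120.0, abs=0.5)

    def test_warm_start_matches_cold_solve(self, baseline_model, closed_loop_sweep):
        """Continuation must not change the solutions."""
        for m in (54.0, 117.0, 180.0):
            cold = baseline_model.solve(map_pressure=m)
            assert cold.converged
            row = closed_loop_sweep.table.loc[
                closed_loop_sweep.table["map_mmHg"] == m
            ].iloc[0]
            assert row["gfr_ml_min"] == pytest.approx(cold.gfr, abs=1e-6)

    def test_open_loop_gfr_strictly_increasing(self, open_loop_sweep):
        g = open_loop_sweep.gfr_values
        assert open_loop_sweep.all_converged
        assert np.all(np.diff(g) > 0.0)

    def test_closed_loop_flatter_than_open_loop(
        self, closed_loop_sweep, open_loop_sweep
    ):
        sel = closed_loop_sweep.map_values >= 90.0
        closed_range = np.ptp(closed_loop_sweep.gfr_values[sel])
        open_range = np.ptp(open_loop_sweep.gfr_values[sel])
        assert closed_range < open_range

    def test_spec_gains_override_model_gains(self, baseline_model):
        sw = map_sweep(
            baseline_model.params,
            SweepSpec(map_min=81.0, map_max=99.0, gains=FeedbackGains.open_loop()),
        )
        # open-loop afferent resistance collapses to the baseline constant
        np.testing.assert_allclose(sw.table["r_tgf"], 0.0)
        np.testing.assert_allclose(
            sw.table["r_afferent_total"],
            baseline_model.params.baseline_afferent_resistance,
        )

    def test_to_csv_round_trip(self, closed_loop_sweep, tmp_path):
        path = tmp_path / "sweep.csv"
        closed_loop_sweep.to_csv(path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["gfr_ml_min"], closed_loop_sweep.gfr_values)


class TestScenarios:
    def test_baseline_scenario_is_identity(self, baseline_model):
        assert apply_scenario(baseline_model.params, BASELINE_SCENARIO) == (
            baseline_model.params
        )

    def test_severe_hypertension_preset(self):
        assert SEVERE_HYPERTENSION.alpha_resistance == 6.0
        assert SEVERE_HYPERTENSION.alpha_feedback == 0.5

    def test_scales_vascular_resistances_only(self, baseline_model):
        p0 = baseline_model.params
        p = apply_scenario(p0, ScenarioSpec(alpha_resistance=6.0))
        assert p.resistances.r_HA == pytest.approx(6 * p0.resistances.r_HA)
        assert p.resistances.r_GE == pytest.approx(6 * p0.resistances.r_GE)
        assert p.resistances.r_EV == pytest.approx(6 * p0.resistances.r_EV)
        assert p.baseline_afferent_resistance == pytest.approx(
            6 * p0.baseline_afferent_resistance
        )
        # tubular and filtration resistances untouched
        assert p.resistances.r_BP == p0.resistances.r_BP
        assert p.resistances.r_DU == p0.resistances.r_DU
        assert p.resistances.r_GB == p0.resistances.r_GB

    def test_scales_gains(self, baseline_model):
        p = apply_scenario(baseline_model.params, ScenarioSpec(alpha_feedback=0.5))
        assert p.feedback_gains == FeedbackGains(0.5, 0.5, 0.5)

    def test_severe_hypertension_lowers_gfr(self, baseline_model, baseline_solution):
        sol = baseline_model.with_scenario(SEVERE_HYPERTENSION).solve()
        assert sol.converged
        assert sol.gfr < baseline_solution.gfr

    def test_negative_multiplier_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScenarioSpec(alpha_resistance=-1.0)


class TestInterpolation:
    def test_exact_at_knots(self, closed_loop_sweep):
        for m, g in zip(closed_loop_sweep.map_values, closed_loop_sweep.gfr_values):
            assert interpolate_curve(closed_loop_sweep, m) == pytest.approx(g)

    def test_no_extrapolation(self, closed_loop_sweep):
        with pytest.raises(InvalidParameterError):
            interpolate_curve(closed_loop_sweep, 50.0)
        with pytest.raises(InvalidParameterError):
            interpolate_curve(closed_loop_sweep, 200.0)

    def test_between_knots_is_bounded(self, closed_loop_sweep):
        # PCHIP is shape-preserving: values stay within the neighbouring knots
        maps = closed_loop_sweep.map_values
        gfr = closed_loop_sweep.gfr_values
        for i in range(len(maps) - 1):
            mid = 0.5 * (maps[i] + maps[i + 1])
            v = interpolate_curve(closed_loop_sweep, mid)
            lo, hi = sorted((gfr[i], gfr[i + 1]))
            assert lo - 1e-9 <= v <= hi + 1e-9


class TestRMSE:
    def test_zero_on_curve(self, closed_loop_sweep):
        obs = pd.DataFrame(
            {
                "map_mmHg": closed_loop_sweep.map_values,
                "gfr_ml_min": closed_loop_sweep.gfr_values,
            }
        )
        assert rmse_against_observations(closed_loop_sweep, obs) < 1e-12

    def test_uniform_shift_returns_shift(self, closed_loop_sweep):
        d = 7.5
        obs = pd.DataFrame(
            {
                "map_mmHg": closed_loop_sweep.map_values,
                "gfr_ml_min": closed_loop_sweep.gfr_values + d,
            }
        )
        assert rmse_against_observations(closed_loop_sweep, obs) == pytest.approx(d)

    def test_empty_table_rejected(self, closed_loop_sweep):
        with pytest.raises(InvalidParameterError):
            rmse_against_observations(
                closed_loop_sweep, pd.DataFrame(columns=["map_mmHg", "gfr_ml_min"])
            )

    def test_missing_column_rejected(self, closed_loop_sweep):
        with pytest.raises(InvalidParameterError):
            rmse_against_observations(
                closed_loop_sweep, pd.DataFrame({"map_mmHg": [90.0]})
            )

    def test_out_of_range_observation_rejected(self, closed_loop_sweep):
        obs = pd.DataFrame({"map_mmHg": [40.0], "gfr_ml_min": [50.0]})
        with pytest.raises(InvalidParameterError):
            rmse_against_observations(closed_loop_sweep, obs)


@pytest.fixture(scope="module")
def grid(baseline_model):
    # small grid over a short MAP window to keep the suite fast
    return baseline_model.sensitivity(
        resistance_alphas=(1.0, 4.0, 8.0),
        feedback_alphas=(0.0, 1.0),
        spec=SweepSpec(map_min=81.0, map_max=117.0, step=9.0),
    )


class TestSensitivity:
    def test_gfr_nonincreasing_in_resistance_alpha(self, grid):
        # monotone on the 1/4/8 grid; the finer-grained full-range invariant
        # (which has a known ~0.6% hump between 1 and 2) lives in
        # test_acceptance.py
        gfr_at_90 = []
        for alpha in sorted(grid.resistance_sweeps):
            t = grid.resistance_sweeps[alpha].table
            assert t["converged"].all()
            gfr_at_90.append(t.loc[t["map_mmHg"] == 90.0, "gfr_ml_min"].iloc[0])
        assert all(a >= b for a, b in zip(gfr_at_90, gfr_at_90[1:]))

    def test_feedback_zero_matches_open_loop(self, grid, baseline_model):
        t = grid.feedback_sweeps[0.0].table
        ref = baseline_model.open_loop().solve()
        at_90 = t.loc[t["map_mmHg"] == 90.0, "gfr_ml_min"].iloc[0]
        assert at_90 == pytest.approx(ref.gfr, abs=1e-6)

    def test_long_frame_and_profiles(self, grid):
        frame = grid.to_frame()
        assert set(frame["factor"]) == {"resistance", "feedback"}
        assert len(frame) == (3 + 2) * 5  # alphas x MAP points
        prof = grid.sodium_profiles
        assert set(prof["node"]) == {"P", "N", "K", "D"}
        assert (prof["map_mmHg"] == 90.0).all()
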