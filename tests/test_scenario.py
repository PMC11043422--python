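"""Two-stage scenario model: collapse, expectation, penalty sweep, min-max."""

import pytest

from bloodnet.instance import restrict_to_scenario
from bloodnet.milp import SolveOptions, solve_single_objective
from bloodnet.scenario import (
    DEFAULT_PENALTY_GRID,
    scenario_report,
    solve_two_stage,
    solve_worst_case,
    sweep_penalty,
)
from bloodnet.synth import generate_tiny
from bloodnet.verify import check_solution

from conftest import chain_instance, tradeoff_instance


class TestCollapse:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_scenario_equals_deterministic_cost(self, seed):
        inst = generate_tiny(seed, {"n_temp": 2, "n_periods": 2})
        det = solve_single_objective(inst, SolveOptions(objective="cost"))
        two = solve_two_stage(inst, penalty=0.0)
        assert two.solver_status == det.solver_status
        if det.solver_status == "optimal":
            assert two.expected_cost == pytest.approx(
                det.objective_cost, rel=1e-6, abs=1e-6
            )

    def test_single_scenario_worst_case_is_identical(self):
        inst = tradeoff_instance()
        a = solve_two_stage(inst, penalty=100.0)
        b = solve_worst_case(inst, penalty=100.0)
        assert a.expected_cost + 100.0 * a.expected_shortage_units == pytest.approx(
            b.expected_cost + 100.0 * b.expected_shortage_units, rel=1e-6
        )


class TestExpectation:
    def test_expected_values_are_probability_weighted_sums(self):
        inst = tradeoff_instance(n_scenarios=2)
        sol = solve_two_stage(inst, penalty=1000.0)
        assert sol.solver_status == "optimal"
        e_cost = sum(
            sol.probabilities[sid] * s.objective_cost
            for sid, s in sol.per_scenario.items()
        )
        e_short = sum(
            sol.probabilities[sid] * sum(s.shortage)
            for sid, s in sol.per_scenario.items()
        )
        assert sol.expected_cost == pytest.approx(e_cost, rel=1e-9)
        assert sol.expected_shortage_units == pytest.approx(e_short, rel=1e-9)
        assert sol.worst_case_shortage == pytest.approx(
            max(sum(s.shortage) for s in sol.per_scenario.values()), abs=1e-9
        )

    def test_first_stage_shared_across_scenarios(self):
        inst = tradeoff_instance(n_scenarios=2)
        sol = solve_two_stage(inst, penalty=1000.0)
        for s in sol.per_scenario.values():
            assert s.open_temp == sol.open_temp
            assert s.open_center == sol.open_center

    def test_every_scenario_passes_the_checker(self):
        inst = tradeoff_instance(n_scenarios=2)
        sol = solve_two_stage(inst, penalty=500.0)
        for sid, s in sol.per_scenario.items():
            rep = check_solution(restrict_to_scenario(inst, sid), s)
            assert rep.passed, (sid, [str(v) for v in rep.violations])

    def test_infeasible_scenario_is_named(self):
        inst = chain_instance(demand=20.0)
        inst.scenarios = [
            inst.scenarios[0].model_copy(update={"probability": 0.5}),
        ] + [
            inst.scenarios[0].model_copy(
                update={"id": "harsh", "probability": 0.5, "demand_multiplier": 5.0}
            )
        ]
        inst.lam = 0.9
        sol = solve_two_stage(inst, penalty=0.0)
        assert sol.solver_status == "infeasible"
        assert "harsh" in sol.infeasibility_hint


class TestPenaltySweep:
    def test_default_grid_contains_case_study_fine(self):
        assert 1_450_000.0 in DEFAULT_PENALTY_GRID

    def test_zero_penalty_equals_pure_expected_cost_optimum(self):
        inst = tradeoff_instance(n_scenarios=2)
        res = sweep_penalty(inst, [0.0])
        base = solve_two_stage(inst, penalty=0.0)
        assert res.rows[0]["expected_cost_excl_penalty"] == pytest.approx(
            base.expected_cost, rel=1e-9
        )

    def test_monotone_shortage_and_cost_and_enumeration(self):
        """Sweep on the designed trade-off instance vs direct enumeration.

        The instance has one collection path into two parallel centers, so
        for each facility configuration the recourse cost is linear in the
        amount routed through each center and the optimum sits at a grid
        vertex; scanning raw routings in integer steps is exhaustive.
        """
        inst = tradeoff_instance()
        grid = [0.0, 100.0, 1000.0, 10_000.0, 1_000_000.0]
        res = sweep_penalty(inst, grid)
        shorts = [r["expected_shortage_units"] for r in res.rows]
        costs = [r["expected_cost_excl_penalty"] for r in res.rows]
        assert all(
            b <= a + 1e-6 for a, b in zip(shorts, shorts[1:])
        ), shorts
        assert all(
            b >= a - 1e-6 for a, b in zip(costs, costs[1:])
        ), costs

        # independent enumeration: configurations x integer raw routings
        alpha_dem, lam_req, beta = 8.0, 2.0, 0.8
        unit1 = (2.0 * 5.0 + 7.0) / beta + 3.0 * 5.0   # via c1, per delivered unit
        unit2 = (4.0 * 5.0 + 7.0) / beta + 1.0 * 5.0   # via c2
        best_by_penalty = []
        for pen in grid:
            best = None
            for open_c2 in (False, True):
                cap1, cap2 = 4.0, (4.0 if open_c2 else 0.0)  # deliverable units
                setup = 1000.0 + (50_000.0 if open_c2 else 0.0)
                for d1 in [x * 0.1 for x in range(0, 41)]:
                    for d2 in [x * 0.1 for x in range(0, 41)]:
                        if d1 > cap1 or d2 > cap2 or d1 + d2 > alpha_dem:
                            continue
                        if d1 + d2 < lam_req - 1e-9:
                            continue
                        if d1 + d2 > 10.0 * beta:  # collection cap 10 raw
                            continue
                        obj = (
                            setup + d1 * unit1 + d2 * unit2
                            + pen * (alpha_dem - d1 - d2)
                        )
                        if best is None or obj < best:
                            best = obj
            best_by_penalty.append(best)
        for row, want in zip(res.rows, best_by_penalty):
            got = row["expected_cost_excl_penalty"] + row["penalty"] * row[
                "expected_shortage_units"
            ]
            assert got == pytest.approx(want, rel=1e-6), row["penalty"]

    def test_empty_or_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_penalty(tradeoff_instance(), [])
        with pytest.raises(ValueError):
            sweep_penalty(tradeoff_instance(), [-1.0])


class TestWorstCase:
    def test_worst_case_at_least_expectation(self):
        inst = tradeoff_instance(n_scenarios=2)
        pen = 1000.0
        e = solve_two_stage(inst, penalty=pen)
        w = solve_worst_case(inst, penalty=pen)
        obj_e = e.expected_cost + pen * e.expected_shortage_units
        w_obj = max(
            s.objective_cost + pen * sum(s.shortage)
            for s in w.per_scenario.values()
        )
        assert w_obj >= obj_e - 1e-6

    def test_min_max_matches_enumeration_on_two_scenarios(self):
        # same enumeration as the sweep test, per scenario, maximized
        inst = tradeoff_instance(n_scenarios=2)
        pen = 2000.0
        w = solve_worst_case(inst, penalty=pen)
        beta = 0.8
        unit1 = (2.0 * 5.0 + 7.0) / beta + 3.0 * 5.0
        unit2 = (4.0 * 5.0 + 7.0) / beta + 1.0 * 5.0
        best = None
        for open_c2 in (False, True):
            cap2 = 4.0 if open_c2 else 0.0
            worst = 0.0
            for mult, setup_mult in ((1.0, 1.0), (1.5, 1.25)):
                alpha_dem = 8.0 * mult
                lam_req = 2.0 * mult
                setup = 1000.0 * setup_mult + (50_000.0 if open_c2 else 0.0)
                scen_best = None
                for d1 in [x * 0.1 for x in range(0, 41)]:
                    for d2 in [x * 0.1 for x in range(0, 41)]:
                        if d1 > 4.0 or d2 > cap2 or d1 + d2 > alpha_dem:
                            continue
                        if d1 + d2 < lam_req - 1e-9 or d1 + d2 > 8.0:
                            continue
                        obj = (
                            setup + d1 * unit1 + d2 * unit2
                            + pen * (alpha_dem - d1 - d2)
                        )
                        if scen_best is None or obj < scen_best:
                            scen_best = obj
                worst = max(worst, scen_best)
            if best is None or worst < best:
                best = worst
        got = max(
            s.objective_cost + pen * sum(s.shortage)
            for s in w.per_scenario.values()
        )
        assert got == pytest.approx(best, rel=1e-6)


class TestScenarioReport:
    def test_single_scenario_report_matches_deterministic(self):
        inst = tradeoff_instance()
        sol = solve_two_stage(inst, penalty=10_000.0)
        rep = scenario_report(sol, inst)
        row = rep["scenarios"][0]
        s = sol.per_scenario["s1"]
        assert row["cost_total"] == pytest.approx(s.objective_cost)
        assert row["shortage_units_total"] == pytest.approx(sum(s.shortage))
        assert row["cost_setup"] + row["cost_transport"] + row[
            "cost_testing"
        ] == pytest.approx(s.objective_cost, rel=1e-9)

    def test_probability_weighted_totals_consistent(self):
        inst = tradeoff_instance(n_scenarios=2)
        sol = solve_two_stage(inst, penalty=1000.0)
        rep = scenario_report(sol, inst)
        e_short = sum(
            r["probability"] * r["shortage_units_total"] for r in rep["scenarios"]
        )
        assert e_short == pytest.approx(sol.expected_shortage_units, rel=1e-9)
        for r in rep["scenarios"]:
            assert sum(r["shortage_by_period"]) == pytest.approx(
                r["shortage_units_total"]
            )
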