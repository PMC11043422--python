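"""Deterministic MILP: closed-form optima, cost arithmetic, big-M, structure."""

import pytest

from bloodnet.instance import validate_instance
from bloodnet.milp import (
    Objective,
    Solution,
    SolveOptions,
    assemble_constraints,
    evaluate_cost,
    evaluate_shortage,
    solve_single_objective,
    tight_big_m,
)
from bloodnet.synth import generate_tiny

from conftest import chain_instance, rich_tiny_instance


class TestChainClosedForms:
    """Single-path chain: the optimum is hand-computable."""

    def test_demand_10_has_no_shortage(self):
        sol = solve_single_objective(
            chain_instance(demand=10.0), SolveOptions(objective="shortage_units")
        )
        assert sol.solver_status == "optimal"
        assert sol.objective_shortage_units == pytest.approx(0.0, abs=1e-6)

    def test_demand_20_shortage_8_ratio_half(self):
        sol = solve_single_objective(
            chain_instance(demand=20.0), SolveOptions(objective="shortage_units")
        )
        assert sol.objective_shortage_units == pytest.approx(8.0, abs=1e-6)
        assert sol.objective_shortage_ratio == pytest.approx(0.5, abs=1e-6)
        # feasible exactly at the lambda bound: 8 delivered >= 0.5 * 16
        assert sum(sol.deliver["c1"]["n1"]) == pytest.approx(8.0, abs=1e-6)

    def test_zero_demand_cost_optimum_opens_nothing(self):
        inst = chain_instance(demand=0.0)
        sol = solve_single_objective(inst, SolveOptions(objective="cost"))
        assert sol.objective_cost == pytest.approx(0.0, abs=1e-9)
        assert not any(sol.open_temp.values())

    def test_lambda_one_forces_zero_shortage(self):
        sol = solve_single_objective(
            chain_instance(demand=10.0, lam=1.0),
            SolveOptions(objective="shortage_units"),
        )
        assert sol.solver_status == "optimal"
        assert sol.objective_shortage_units == pytest.approx(0.0, abs=1e-6)

    def test_lambda_one_unattainable_reports_hint(self):
        sol = solve_single_objective(
            chain_instance(demand=20.0, lam=1.0),
            SolveOptions(objective="shortage_units"),
        )
        assert sol.solver_status == "infeasible"
        assert "period 0" in sol.infeasibility_hint


class TestEvaluateCost:
    def _cost_fixture(self):
        from bloodnet.instance import FacilitySite, NetworkInstance, SiteKind

        inst = NetworkInstance(
            id="cost",
            sites=[
                FacilitySite(id="t1", kind=SiteKind.temporary_collection,
                             exists=False, setup_cost=2_000_000.0),
                FacilitySite(id="c1", kind=SiteKind.blood_center,
                             exists=False, setup_cost=1_000_000_000.0),
                FacilitySite(id="n1", kind=SiteKind.treatment_center, exists=True),
            ],
            periods=[24.0],
            unit_transport_cost=5000.0,
            unit_test_cost=5000.0,
            vehicle_capacity=100.0,
        )
        inst.capa_temp["t1"] = [200.0]
        inst.capd_center["c1"] = [200.0]
        inst.capf_treat["n1"] = 200.0
        inst.demand = [0.0]
        inst.dist_coll_center["t1"] = {"c1": 10.0}
        inst.dist_center_treat["c1"] = {"n1": 10.0}
        return inst

    def test_empty_solution_costs_nothing(self):
        inst = self._cost_fixture()
        sol = Solution(shortage=[0.0])
        assert evaluate_cost(inst, sol) == 0.0

    def test_hand_arithmetic_with_case_unit_costs(self):
        # setup 2e6 + 1e9, 100 units over 10 km at 5000/unit km, 100 tested
        inst = self._cost_fixture()
        sol = Solution(
            open_temp={"t1": True},
            open_center={"c1": True},
            ship_temp={"t1": {"c1": [100.0]}},
            shortage=[0.0],
        )
        assert evaluate_cost(inst, sol) == pytest.approx(1_007_500_000.0)

    def test_integral_vehicles_ceil_trip_count(self):
        inst = self._cost_fixture()
        sol = Solution(ship_temp={"t1": {"c1": [101.0]}}, shortage=[0.0])
        # ceil(101/100) = 2 trips * 10 km * 5000
        transport = evaluate_cost(inst, sol, integral_vehicles=True)
        assert transport == pytest.approx(2 * 10 * 5000 + 101 * 5000)

    def test_missing_distance_errors(self):
        inst = self._cost_fixture()
        sol = Solution(ship_temp={"t1": {"cX": [5.0]}}, shortage=[0.0])
        with pytest.raises(KeyError):
            evaluate_cost(inst, sol)


class TestEvaluateShortage:
    def test_direct_formula(self):
        inst = chain_instance(n_periods=4)
        inst.demand = [20.0, 12.5, 10.0, 12.5]  # alpha*Dem = 16, 10, 8, 10
        sol = Solution(shortage=[8.0, 0.0, 4.0, 0.0])
        ratio, units = evaluate_shortage(inst, sol)
        assert ratio == pytest.approx(1.0)
        assert units == pytest.approx(12.0)

    def test_zero_demand_period_contributes_zero(self):
        inst = chain_instance(n_periods=2)
        inst.demand = [10.0, 0.0]
        ratio, units = evaluate_shortage(inst, Solution(shortage=[0.0, 0.0]))
        assert (ratio, units) == (0.0, 0.0)

    def test_shortage_without_demand_is_inconsistent(self):
        inst = chain_instance(n_periods=1)
        inst.demand = [0.0]
        with pytest.raises(ValueError, match="zero-demand"):
            evaluate_shortage(inst, Solution(shortage=[1.0]))


class TestBigM:
    def test_collection_linkage_equals_capacity(self):
        inst = rich_tiny_instance()
        M = tight_big_m(inst)
        assert M[("eq2", "t1", 0)] == inst.capa_temp["t1"][0]
        assert M[("eq4", "p1", 1)] == inst.capa_perm["p1"][1]

    def test_zero_capacities_force_zero_m(self):
        inst = chain_instance(capa=0.0, capd=0.0, capf=0.0, demand=0.0)
        M = tight_big_m(inst)
        assert all(v == 0.0 for v in M.values())

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_invariant_to_looser_m(self, seed):
        inst = generate_tiny(seed, {"n_temp": 2, "n_center": 2, "n_periods": 2})
        loose = {k: 1e9 for k in tight_big_m(inst)}
        for objective in (Objective.shortage_units, Objective.cost):
            tight_sol = solve_single_objective(inst, SolveOptions(objective=objective))
            sys = assemble_constraints(inst, big_m=loose)
            from bloodnet.milp import _objective_coeffs

            sys.model.set_objective(_objective_coeffs(inst, objective, False))
            status, values, obj = sys.model.solve(1e-9)
            assert status == tight_sol.solver_status
            if status != "optimal":
                continue
            want = (
                tight_sol.objective_cost
                if objective == Objective.cost
                else tight_sol.objective_shortage_units
            )
            assert obj == pytest.approx(want, rel=1e-6, abs=1e-6)


class TestAssemblyStructure:
    def test_row_counts_on_one_of_each(self):
        inst = rich_tiny_instance()  # 1 temp, 1 perm, 1 center, 1 treat, 1 field; T=2
        counts = assemble_constraints(inst).counts
        T = 2
        assert counts["eq1"] == counts["eq2"] == T          # per (i, t)
        assert counts["eq3"] == counts["eq4"] == T          # per (u, t)
        assert counts["eq5"] == counts["eq6"] == T
        assert counts["eq7"] == counts["eq12"] == T         # per (z, t)
        assert counts["eq8"] == counts["eq10"] == T         # per (i, z, t)
        assert counts["eq9"] == counts["eq11"] == T
        assert counts["eq13"] == 2 * T                      # per (n, t), 2 treat nodes
        assert counts["eq14"] == counts["eq18"] == T
        assert counts["eq15"] == 2 * T                      # per (z, n, t)
        assert counts["eq17"] == T                          # field hospital only

    def test_existing_sites_emit_no_linkage_rows(self):
        inst = rich_tiny_instance()
        inst.sites = [s.model_copy(update={"exists": True, "setup_cost": 0.0})
                      for s in inst.sites]
        counts = assemble_constraints(inst).counts
        for fam in ("eq2", "eq4", "eq8", "eq9", "eq10", "eq11", "eq15", "eq17"):
            assert counts[fam] == 0, fam


class TestMonotonicity:
    def test_more_capacity_never_increases_shortage(self):
        base = chain_instance(demand=20.0)
        lo = solve_single_objective(base, SolveOptions(objective="shortage_units"))
        for field, key in (("capa_temp", "t1"), ("capd_center", "c1")):
            inst = base.model_copy(deep=True)
            getattr(inst, field)[key][0] += 5.0
            hi = solve_single_objective(inst, SolveOptions(objective="shortage_units"))
            assert hi.objective_shortage_units <= lo.objective_shortage_units + 1e-6

    def test_raising_lambda_never_lowers_cost(self):
        prev = -1.0
        for lam in (0.1, 0.3, 0.5):
            inst = chain_instance(demand=20.0, lam=lam)
            sol = solve_single_objective(inst, SolveOptions(objective="cost"))
            assert sol.solver_status == "optimal"
            assert sol.objective_cost >= prev - 1e-6
            prev = sol.objective_cost


def test_solutions_round_trip_through_json(tmp_path):
    from bloodnet.milp import load_solution, save_solution

    sol = solve_single_objective(
        chain_instance(demand=20.0), SolveOptions(objective="cost")
    )
    p = tmp_path / "sol.json"
    save_solution(sol, p)
    assert load_solution(p) == sol


def test_generated_instances_validate_before_solve():
    inst = generate_tiny(0)
    inst.capa_temp[inst.temp_sites[0].id][0] = -1.0
    with pytest.raises(ValueError, match="invalid instance"):
        solve_single_objective(inst)
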