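"""Bi-objective drivers: individual optima, weighted scalarization, epsilon-constraint.

Cost and shortage conflict: extra collection sites, blood centers and field
hospitals reduce unmet transfusion demand but raise setup and transport
spending.  The front between the two objectives is traced by scalarization:

* :func:`ideal_points` — the two single-objective optima (the ideal point);
* :func:`solve_weighted` — minimize ``w_c * cost/c* + w_s * shortage/s*``
  (ideal-point normalization, since raw costs ~1e9 dwarf unit shortages),
  optionally under a hard cost bound — the "weighted method with the cost
  objective as a constraint";
* :func:`solve_epsilon_front` — minimize shortage subject to ``cost <= eps``
  over a grid of eps values, lexicographically tie-broken toward lower cost,
  then non-dominance filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .instance import NetworkInstance
from .milp import (
    InfeasibleError,
    Objective,
    Solution,
    SolveOptions,
    _objective_coeffs,
    _extract_solution,
    assemble_constraints,
    evaluate_cost,
    evaluate_shortage,
    infeasibility_hint,
    solve_single_objective,
)

_TIE_TOL = 1e-9


@dataclass
class ParetoPoint:
    """One (cost, shortage) outcome with its underlying solution."""

    cost: float
    shortage: float
    solution: Solution
    epsilon: Optional[float] = None

    def dominates(self, other: "ParetoPoint", tol: float = _TIE_TOL) -> bool:
        """Weak dominance: <= in both objectives, strictly < in at least one."""
        le_cost = self.cost <= other.cost + tol
        le_short = self.shortage <= other.shortage + tol
        lt_any = self.cost < other.cost - tol or self.shortage < other.shortage - tol
        return le_cost and le_short and lt_any


@dataclass
class ParetoFront:
    points: list[ParetoPoint] = field(default_factory=list)
    ideal: tuple[float, float] = (0.0, 0.0)
    metric: Objective = Objective.shortage_units

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


def _shortage_value(sol: Solution, metric: Objective) -> float:
    if metric == Objective.shortage_ratio:
        return sol.objective_shortage_ratio
    return sol.objective_shortage_units


def ideal_points(
    inst: NetworkInstance,
    opts: Optional[SolveOptions] = None,
    metric: Objective = Objective.shortage_units,
) -> tuple[float, float]:
    """The two single-objective optima (cost*, shortage*).

    Each value is a valid lower bound on its objective over all feasible
    solutions.  Raises :class:`InfeasibleError` on an infeasible instance.
    """
    opts = opts or SolveOptions()
    sols = anchor_solutions(inst, opts, metric)
    return sols[0].objective_cost, _shortage_value(sols[1], metric)


def anchor_solutions(
    inst: NetworkInstance,
    opts: Optional[SolveOptions] = None,
    metric: Objective = Objective.shortage_units,
) -> tuple[Solution, Solution]:
    """(cost-optimal solution, shortage-optimal solution), solved independently."""
    opts = opts or SolveOptions()
    out = []
    for obj in (Objective.cost, metric):
        sol = solve_single_objective(
            inst, opts.model_copy(update={"objective": obj})
        )
        if sol.solver_status != "optimal":
            raise InfeasibleError(
                f"single-objective solve ({obj.value}) ended {sol.solver_status}: "
                f"{sol.infeasibility_hint or infeasibility_hint(inst)}"
            )
        out.append(sol)
    return out[0], out[1]


def _scalarized_solve(
    inst: NetworkInstance,
    opts: SolveOptions,
    metric: Objective,
    w_cost: float,
    w_short: float,
    norm_cost: float,
    norm_short: float,
    cost_bound: Optional[float] = None,
    shortage_bound: Optional[float] = None,
) -> Solution:
    sys = assemble_constraints(inst, integral_vehicles=opts.integral_vehicles)
    cost_coeffs = _objective_coeffs(inst, Objective.cost, opts.integral_vehicles)
    short_coeffs = _objective_coeffs(inst, metric, opts.integral_vehicles)
    obj: dict = {}
    for k, v in cost_coeffs.items():
        obj[k] = obj.get(k, 0.0) + w_cost * v / norm_cost
    for k, v in short_coeffs.items():
        obj[k] = obj.get(k, 0.0) + w_short * v / norm_short
    if cost_bound is not None:
        sys.model.add_le(dict(cost_coeffs), cost_bound, "cost_bound")
    if shortage_bound is not None:
        sys.model.add_le(dict(short_coeffs), shortage_bound, "shortage_bound")
    sys.model.set_objective(obj)
    status, values, _ = sys.model.solve(opts.mip_gap, opts.time_limit)
    if status != "optimal" or not values:
        raise InfeasibleError(f"scalarized solve ended {status}")
    sol = _extract_solution(inst, values)
    sol.solver_status = "optimal"
    sol.objective_cost = evaluate_cost(inst, sol, opts.integral_vehicles)
    ratio, units = evaluate_shortage(inst, sol)
    sol.objective_shortage_ratio = ratio
    sol.objective_shortage_units = units
    return sol


def solve_weighted(
    inst: NetworkInstance,
    w_cost: float,
    w_short: float,
    cost_bound: Optional[float] = None,
    opts: Optional[SolveOptions] = None,
    metric: Objective = Objective.shortage_units,
) -> ParetoPoint:
    """Weighted-sum scalarization with ideal-point normalization.

    Each objective is divided by max(its ideal value, 1) before weighting.
    With ``cost_bound`` the hard constraint cost <= cost_bound is added (the
    hybrid "weighted method with cost as a constraint").
    """
    if w_cost < 0 or w_short < 0 or (w_cost == 0 and w_short == 0):
        raise ValueError("weights must be >= 0 and not both zero")
    opts = opts or SolveOptions()
    cost_star, short_star = ideal_points(inst, opts, metric)
    if cost_bound is not None and cost_bound < cost_star * (1 - 1e-9) - 1e-6:
        raise InfeasibleError(
            f"cost bound {cost_bound} is below the minimum attainable cost {cost_star}"
        )
    sol = _scalarized_solve(
        inst, opts, metric, w_cost, w_short,
        max(cost_star, 1.0), max(short_star, 1.0), cost_bound=cost_bound,
    )
    return ParetoPoint(
        cost=sol.objective_cost,
        shortage=_shortage_value(sol, metric),
        solution=sol,
        epsilon=cost_bound,
    )


def solve_epsilon_front(
    inst: NetworkInstance,
    n_points: int = 5,
    epsilons: Optional[Sequence[float]] = None,
    opts: Optional[SolveOptions] = None,
    metric: Objective = Objective.shortage_units,
) -> ParetoFront:
    """Trace the Pareto front by the epsilon-constraint method.

    For each cost bound eps, minimize shortage subject to cost <= eps, then
    re-minimize cost at that shortage level (lexicographic tie-break).  The
    default grid is equally spaced between the cost-optimal cost and the
    cost of the shortage-anchored solution.
    """
    opts = opts or SolveOptions()
    if epsilons is None and n_points < 2:
        raise ValueError("n_points must be >= 2")
    cost_sol, short_sol = anchor_solutions(inst, opts, metric)
    cost_star = cost_sol.objective_cost
    short_star = _shortage_value(short_sol, metric)

    if epsilons is None:
        hi = max(short_sol.objective_cost, cost_star)
        if hi <= cost_star + 1e-9:
            grid = [cost_star]
        else:
            step = (hi - cost_star) / (n_points - 1)
            grid = [cost_star + i * step for i in range(n_points)]
    else:
        grid = sorted(epsilons)
        if not grid:
            raise ValueError("epsilon grid must be non-empty")

    points: list[ParetoPoint] = []
    for eps in grid:
        if eps < cost_star * (1 - 1e-9) - 1e-6:
            raise InfeasibleError(
                f"epsilon {eps} is below the minimum attainable cost {cost_star}"
            )
        eps_slack = eps * (1 + 1e-9) + 1e-6
        first = _scalarized_solve(
            inst, opts, metric, 0.0, 1.0, 1.0, 1.0, cost_bound=eps_slack
        )
        s_val = _shortage_value(first, metric)
        # tie-break: cheapest solution attaining this shortage level
        second = _scalarized_solve(
            inst, opts, metric, 1.0, 0.0, 1.0, 1.0,
            cost_bound=eps_slack,
            shortage_bound=s_val * (1 + 1e-9) + 1e-6,
        )
        points.append(
            ParetoPoint(
                cost=second.objective_cost,
                shortage=_shortage_value(second, metric),
                solution=second,
                epsilon=eps,
            )
        )
    front = filter_nondominated(points, metric=metric)
    front.ideal = (cost_star, short_star)
    return front


def filter_nondominated(
    points: Sequence[ParetoPoint],
    metric: Objective = Objective.shortage_units,
) -> ParetoFront:
    """Keep exactly the points not weakly dominated by any other; sort by cost.

    Idempotent; duplicate (cost, shortage) pairs are collapsed to one point.
    """
    kept: list[ParetoPoint] = []
    for p in points:
        if any(q.dominates(p) for q in points if q is not p):
            continue
        if any(
            abs(q.cost - p.cost) <= _TIE_TOL and abs(q.shortage - p.shortage) <= _TIE_TOL
            for q in kept
        ):
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.cost, p.shortage))
    ideal = (
        min((p.cost for p in kept), default=0.0),
        min((p.shortage for p in kept), default=0.0),
    )
    return ParetoFront(points=kept, ideal=ideal, metric=metric)
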