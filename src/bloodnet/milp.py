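"""Deterministic single-scenario MILP: assembly, solving, objective evaluation.

The model locates facilities (binary open decisions for candidate temporary
collection sites X_i, permanent facilities Y_j, blood centers W_z and field
hospitals F_a) and routes blood through three layers per period t:

    collection (CH_it at temporary sites, BH_ut at permanent facilities)
      -> shipments to blood centers (QT_izt, QC_uzt), tested there
      -> deliveries to treatment nodes (TH_znt), against transfusion
         demand alpha * Dem_t, with per-center inventory IN_zt carried
         between periods and per-period shortage IB_t.

Constraint families (labels used throughout the package):

    eq1   CH_it <= capa_it                      collection capacity, temporary
    eq2   CH_it <= M X_i                        open linkage, temporary
    eq3   BH_ut <= capa_ut                      collection capacity, permanent
    eq4   BH_ut <= M Y_u                        open linkage, permanent
    eq5   CH_it = sum_z QT_izt                  conservation, temporary
    eq6   BH_ut = sum_z QC_uzt                  conservation, permanent
    eq7   sum_i QT_izt + sum_u QC_uzt <= Capd_zt   center intake capacity
    eq8   QT_izt <= M W_z                       shipment requires open center
    eq9   QC_uzt <= M W_z                       shipment requires open center
    eq10  QT_izt <= M X_i                       shipment requires open source
    eq11  QC_uzt <= M Y_u                       shipment requires open source
    eq12  beta*(intake) + IN_{z,t-1} - sum_n TH_znt = IN_zt   inventory balance
    eq13  sum_z TH_znt <= Capf_n                treatment capacity
    eq14  sum_zn TH_znt + IB_t = alpha*Dem_t    demand / shortage accounting
    eq15  TH_znt <= M W_z                       delivery requires open center
    eq17  TH_znt <= M F_a                       delivery requires open field hospital
    eq18  sum_zn TH_znt >= lam*alpha*Dem_t      minimum service level

Treatment nodes are existing treatment centers (always open; no linkage
rows) plus candidate field hospitals, so the destination-open family is
eq17; linkage rows are likewise omitted for any existing facility.
Big-M values are per-row tight capacity bounds (see :func:`tight_big_m`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from ._linmodel import LinearModel
from .instance import NetworkInstance, validate_instance

FAMILIES = [
    "eq1", "eq2", "eq3", "eq4", "eq5", "eq6", "eq7", "eq8", "eq9",
    "eq10", "eq11", "eq12", "eq13", "eq14", "eq15", "eq17", "eq18",
]


class InfeasibleError(RuntimeError):
    """The model (or a scalarized/bounded variant of it) has no feasible point."""


class Objective(str, Enum):
    cost = "cost"
    shortage_ratio = "shortage_ratio"
    shortage_units = "shortage_units"


class SolveOptions(BaseModel):
    model_config = ConfigDict(frozen=True)

    objective: Objective = Objective.shortage_units
    mip_gap: float = 1e-6
    time_limit: Optional[float] = None
    integral_vehicles: bool = False
    solver_backend: str = "scipy-highs"


class Solution(BaseModel):
    """One deterministic solution: open decisions, flows, inventory, shortage."""

    model_config = ConfigDict(frozen=False)

    instance_id: str = ""
    open_temp: dict[str, bool] = Field(default_factory=dict)
    open_perm: dict[str, bool] = Field(default_factory=dict)
    open_center: dict[str, bool] = Field(default_factory=dict)
    open_field: dict[str, bool] = Field(default_factory=dict)
    collected_temp: dict[str, list[float]] = Field(default_factory=dict)
    collected_perm: dict[str, list[float]] = Field(default_factory=dict)
    ship_temp: dict[str, dict[str, list[float]]] = Field(default_factory=dict)
    ship_perm: dict[str, dict[str, list[float]]] = Field(default_factory=dict)
    deliver: dict[str, dict[str, list[float]]] = Field(default_factory=dict)
    inventory: dict[str, list[float]] = Field(default_factory=dict)
    shortage: list[float] = Field(default_factory=list)
    objective_cost: float = 0.0
    objective_shortage_ratio: float = 0.0
    objective_shortage_units: float = 0.0
    solver_status: str = "optimal"
    infeasibility_hint: Optional[str] = None
    solve_options: Optional[dict] = None

    def is_open(self, site_id: str) -> bool:
        for table in (self.open_temp, self.open_perm, self.open_center, self.open_field):
            if site_id in table:
                return table[site_id]
        return True  # existing treatment centers carry no open variable


def save_solution(sol: Solution, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(sol.model_dump(mode="json"), fh, sort_keys=True, indent=2)
        fh.write("\n")


def load_solution(path: str | Path) -> Solution:
    return Solution.model_validate(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# big-M


def tight_big_m(inst: NetworkInstance) -> dict[tuple, float]:
    """Tightest valid big-M per linkage row.

    Each value is an upper bound on the linked flow variable valid in every
    feasible solution, so replacing it by anything larger cannot change the
    optimum.
    """
    M: dict[tuple, float] = {}
    T = inst.n_periods
    centers = [s.id for s in inst.center_sites]
    for s in inst.temp_sites:
        for t in range(T):
            M[("eq2", s.id, t)] = inst.capa_temp[s.id][t]
            for z in centers:
                M[("eq8", s.id, z, t)] = min(
                    inst.capa_temp[s.id][t], inst.capd_center[z][t]
                )
                M[("eq10", s.id, z, t)] = M[("eq8", s.id, z, t)]
    for s in inst.perm_sites:
        for t in range(T):
            M[("eq4", s.id, t)] = inst.capa_perm[s.id][t]
            for z in centers:
                M[("eq9", s.id, z, t)] = min(
                    inst.capa_perm[s.id][t], inst.capd_center[z][t]
                )
                M[("eq11", s.id, z, t)] = M[("eq9", s.id, z, t)]
    for z in centers:
        cum = inst.init_inventory(z)
        for t in range(T):
            cum += inst.beta * inst.capd_center[z][t]
            dem = inst.transfusion_demand(t)
            for n in inst.treat_sites:
                M[("eq15", z, n.id, t)] = min(inst.capf_treat[n.id], cum, dem)
                M[("eq17", z, n.id, t)] = M[("eq15", z, n.id, t)]
    return M


# ---------------------------------------------------------------------------
# model assembly


@dataclass
class ConstraintSystem:
    """Assembled MILP plus row counts per constraint family."""

    model: LinearModel
    counts: dict[str, int] = dc_field(default_factory=dict)
    big_m: dict[tuple, float] = dc_field(default_factory=dict)


_FLOW_PREFIXES = {"CH", "BH", "QT", "QC", "TH", "IN", "IB", "TRIPS"}


def _tag_name(name: tuple, tag: Optional[str]) -> tuple:
    if tag is not None and name[0] in _FLOW_PREFIXES:
        return name + (tag,)
    return name


class _TagView:
    """LinearModel facade that suffixes flow variables with a scenario tag.

    Binary (first-stage) variables keep their untagged names and are created
    once, so scenario replicas of the constraint system share them.
    """

    def __init__(self, base: LinearModel, tag: Optional[str]):
        self.base = base
        self.tag = tag

    def _map(self, coeffs: dict) -> dict:
        return {_tag_name(k, self.tag): v for k, v in coeffs.items()}

    def var(self, name: tuple, **kw) -> None:
        self.base.var(_tag_name(name, self.tag), **kw)

    def binary(self, name: tuple, fixed=None) -> None:
        if not self.base.has(name):
            self.base.binary(name, fixed)

    def add_le(self, coeffs: dict, rhs: float, label: str = "") -> None:
        self.base.add_le(self._map(coeffs), rhs, label)

    def add_ge(self, coeffs: dict, rhs: float, label: str = "") -> None:
        self.base.add_ge(self._map(coeffs), rhs, label)

    def add_eq(self, coeffs: dict, rhs: float, label: str = "") -> None:
        self.base.add_eq(self._map(coeffs), rhs, label)


def assemble_constraints(
    inst: NetworkInstance,
    integral_vehicles: bool = False,
    big_m: Optional[dict[tuple, float]] = None,
    model: Optional[LinearModel] = None,
    tag: Optional[str] = None,
) -> ConstraintSystem:
    """Build the variable set and all constraint rows for one scenario.

    Linkage rows (eq2/4/8/9/10/11/15/17) are emitted only for candidate
    facilities; existing ones are open by construction (binaries fixed to 1).
    When ``model``/``tag`` are given, rows are appended to the shared model
    with scenario-suffixed flow variables (two-stage assembly).
    """
    m = _TagView(model if model is not None else LinearModel(), tag)
    M = big_m if big_m is not None else tight_big_m(inst)
    T = inst.n_periods
    temps = inst.temp_sites
    perms = inst.perm_sites
    centers = inst.center_sites
    treats = inst.treat_sites
    counts = {f: 0 for f in FAMILIES}

    def emit(family: str, kind: str, coeffs: dict, rhs: float, idx: tuple) -> None:
        label = f"{family}{list(idx)}" + (f"@{tag}" if tag else "")
        if kind == "le":
            m.add_le(coeffs, rhs, label)
        elif kind == "ge":
            m.add_ge(coeffs, rhs, label)
        else:
            m.add_eq(coeffs, rhs, label)
        counts[family] += 1

    for s in temps:
        m.binary(("X", s.id), fixed=True if s.exists else None)
    for s in perms:
        m.binary(("Y", s.id), fixed=True if s.exists else None)
    for s in centers:
        m.binary(("W", s.id), fixed=True if s.exists else None)
    for s in inst.field_sites:
        m.binary(("F", s.id), fixed=True if s.exists else None)

    for t in range(T):
        for s in temps:
            m.var(("CH", s.id, t))
        for s in perms:
            m.var(("BH", s.id, t))
        for s in temps:
            for z in centers:
                m.var(("QT", s.id, z.id, t))
        for s in perms:
            for z in centers:
                m.var(("QC", s.id, z.id, t))
        for z in centers:
            for n in treats:
                m.var(("TH", z.id, n.id, t))
        for z in centers:
            m.var(("IN", z.id, t))
        m.var(("IB", t))

    if integral_vehicles:
        for t in range(T):
            for s in temps:
                for z in centers:
                    m.var(("TRIPS", s.id, z.id, t), integer=True)
                    m.add_le(
                        {("QT", s.id, z.id, t): 1.0,
                         ("TRIPS", s.id, z.id, t): -inst.vehicle_capacity},
                        0.0, "trips")
            for s in perms:
                for z in centers:
                    m.var(("TRIPS", s.id, z.id, t), integer=True)
                    m.add_le(
                        {("QC", s.id, z.id, t): 1.0,
                         ("TRIPS", s.id, z.id, t): -inst.vehicle_capacity},
                        0.0, "trips")
            for z in centers:
                for n in treats:
                    m.var(("TRIPS", z.id, n.id, t), integer=True)
                    m.add_le(
                        {("TH", z.id, n.id, t): 1.0,
                         ("TRIPS", z.id, n.id, t): -inst.vehicle_capacity},
                        0.0, "trips")

    for t in range(T):
        for s in temps:
            emit("eq1", "le", {("CH", s.id, t): 1.0}, inst.capa_temp[s.id][t], (s.id, t))
            if not s.exists:
                emit("eq2", "le",
                     {("CH", s.id, t): 1.0, ("X", s.id): -M[("eq2", s.id, t)]},
                     0.0, (s.id, t))
        for s in perms:
            emit("eq3", "le", {("BH", s.id, t): 1.0}, inst.capa_perm[s.id][t], (s.id, t))
            if not s.exists:
                emit("eq4", "le",
                     {("BH", s.id, t): 1.0, ("Y", s.id): -M[("eq4", s.id, t)]},
                     0.0, (s.id, t))
        for s in temps:
            coeffs = {("CH", s.id, t): 1.0}
            for z in centers:
                coeffs[("QT", s.id, z.id, t)] = -1.0
            emit("eq5", "eq", coeffs, 0.0, (s.id, t))
        for s in perms:
            coeffs = {("BH", s.id, t): 1.0}
            for z in centers:
                coeffs[("QC", s.id, z.id, t)] = -1.0
            emit("eq6", "eq", coeffs, 0.0, (s.id, t))
        for z in centers:
            coeffs: dict = {}
            for s in temps:
                coeffs[("QT", s.id, z.id, t)] = 1.0
            for s in perms:
                coeffs[("QC", s.id, z.id, t)] = 1.0
            emit("eq7", "le", coeffs, inst.capd_center[z.id][t], (z.id, t))
        for s in temps:
            for z in centers:
                if not z.exists:
                    emit("eq8", "le",
                         {("QT", s.id, z.id, t): 1.0,
                          ("W", z.id): -M[("eq8", s.id, z.id, t)]},
                         0.0, (s.id, z.id, t))
                if not s.exists:
                    emit("eq10", "le",
                         {("QT", s.id, z.id, t): 1.0,
                          ("X", s.id): -M[("eq10", s.id, z.id, t)]},
                         0.0, (s.id, z.id, t))
        for s in perms:
            for z in centers:
                if not z.exists:
                    emit("eq9", "le",
                         {("QC", s.id, z.id, t): 1.0,
                          ("W", z.id): -M[("eq9", s.id, z.id, t)]},
                         0.0, (s.id, z.id, t))
                if not s.exists:
                    emit("eq11", "le",
                         {("QC", s.id, z.id, t): 1.0,
                          ("Y", s.id): -M[("eq11", s.id, z.id, t)]},
                         0.0, (s.id, z.id, t))
        for z in centers:
            coeffs = {("IN", z.id, t): -1.0}
            for s in temps:
                coeffs[("QT", s.id, z.id, t)] = inst.beta
            for s in perms:
                coeffs[("QC", s.id, z.id, t)] = inst.beta
            if t > 0:
                coeffs[("IN", z.id, t - 1)] = 1.0
            for n in treats:
                coeffs[("TH", z.id, n.id, t)] = -1.0
            emit("eq12", "eq", coeffs,
                 -inst.init_inventory(z.id) if t == 0 else 0.0, (z.id, t))
        for n in treats:
            coeffs = {("TH", z.id, n.id, t): 1.0 for z in centers}
            emit("eq13", "le", coeffs, inst.capf_treat[n.id], (n.id, t))
        dem = inst.transfusion_demand(t)
        coeffs = {("TH", z.id, n.id, t): 1.0 for z in centers for n in treats}
        coeffs[("IB", t)] = 1.0
        emit("eq14", "eq", coeffs, dem, (t,))
        for z in centers:
            for n in treats:
                if not z.exists:
                    emit("eq15", "le",
                         {("TH", z.id, n.id, t): 1.0,
                          ("W", z.id): -M[("eq15", z.id, n.id, t)]},
                         0.0, (z.id, n.id, t))
                if n.kind.value == "field_hospital" and not n.exists:
                    emit("eq17", "le",
                         {("TH", z.id, n.id, t): 1.0,
                          ("F", n.id): -M[("eq17", z.id, n.id, t)]},
                         0.0, (z.id, n.id, t))
        coeffs = {("TH", z.id, n.id, t): 1.0 for z in centers for n in treats}
        emit("eq18", "ge", coeffs, inst.lam * dem, (t,))

    return ConstraintSystem(model=m.base, counts=counts, big_m=M)


def _objective_coeffs(inst: NetworkInstance, objective: Objective,
                      integral_vehicles: bool, tag: Optional[str] = None) -> dict:
    coeffs: dict = {}
    T = inst.n_periods
    if objective == Objective.cost:
        for s in inst.temp_sites:
            if not s.exists:
                coeffs[("X", s.id)] = s.setup_cost
        for s in inst.perm_sites:
            if not s.exists:
                coeffs[("Y", s.id)] = s.setup_cost
        for s in inst.center_sites:
            if not s.exists:
                coeffs[("W", s.id)] = s.setup_cost
        for s in inst.field_sites:
            if not s.exists:
                coeffs[("F", s.id)] = s.setup_cost
        c = inst.unit_transport_cost
        for t in range(T):
            for s in inst.temp_sites:
                for z in inst.center_sites:
                    d = inst.distance(s.id, z.id)
                    if integral_vehicles:
                        coeffs[("TRIPS", s.id, z.id, t)] = d * c
                    else:
                        coeffs[("QT", s.id, z.id, t)] = d * c
                    coeffs[("QT", s.id, z.id, t)] = coeffs.get(
                        ("QT", s.id, z.id, t), 0.0) + inst.unit_test_cost
            for s in inst.perm_sites:
                for z in inst.center_sites:
                    d = inst.distance(s.id, z.id)
                    if integral_vehicles:
                        coeffs[("TRIPS", s.id, z.id, t)] = d * c
                    else:
                        coeffs[("QC", s.id, z.id, t)] = d * c
                    coeffs[("QC", s.id, z.id, t)] = coeffs.get(
                        ("QC", s.id, z.id, t), 0.0) + inst.unit_test_cost
            for z in inst.center_sites:
                for n in inst.treat_sites:
                    d = inst.distance(z.id, n.id)
                    if integral_vehicles:
                        coeffs[("TRIPS", z.id, n.id, t)] = d * c
                    else:
                        coeffs[("TH", z.id, n.id, t)] = d * c
    elif objective == Objective.shortage_units:
        for t in range(T):
            coeffs[("IB", t)] = 1.0
    else:  # shortage_ratio
        for t in range(T):
            dem = inst.transfusion_demand(t)
            if dem > 0:
                coeffs[("IB", t)] = 1.0 / dem
    return {_tag_name(k, tag): v for k, v in coeffs.items()}


# ---------------------------------------------------------------------------
# solving


def _round_clip(v: float, tol: float = 1e-7) -> float:
    if abs(v) < tol:
        return 0.0
    r = round(v)
    if abs(v - r) < tol:
        return float(r)
    return v


def _extract_solution(
    inst: NetworkInstance, values: dict, tag: Optional[str] = None
) -> Solution:
    T = inst.n_periods

    def v(*name) -> float:
        return values[_tag_name(tuple(name), tag)]

    sol = Solution(instance_id=inst.id)
    for s in inst.temp_sites:
        sol.open_temp[s.id] = v("X", s.id) > 0.5
        sol.collected_temp[s.id] = [_round_clip(v("CH", s.id, t)) for t in range(T)]
    for s in inst.perm_sites:
        sol.open_perm[s.id] = v("Y", s.id) > 0.5
        sol.collected_perm[s.id] = [_round_clip(v("BH", s.id, t)) for t in range(T)]
    for s in inst.center_sites:
        sol.open_center[s.id] = v("W", s.id) > 0.5
        sol.inventory[s.id] = [_round_clip(v("IN", s.id, t)) for t in range(T)]
    for s in inst.field_sites:
        sol.open_field[s.id] = v("F", s.id) > 0.5
    for s in inst.temp_sites:
        sol.ship_temp[s.id] = {
            z.id: [_round_clip(v("QT", s.id, z.id, t)) for t in range(T)]
            for z in inst.center_sites
        }
    for s in inst.perm_sites:
        sol.ship_perm[s.id] = {
            z.id: [_round_clip(v("QC", s.id, z.id, t)) for t in range(T)]
            for z in inst.center_sites
        }
    for z in inst.center_sites:
        sol.deliver[z.id] = {
            n.id: [_round_clip(v("TH", z.id, n.id, t)) for t in range(T)]
            for n in inst.treat_sites
        }
    sol.shortage = [_round_clip(v("IB", t)) for t in range(T)]
    return sol


def infeasibility_hint(inst: NetworkInstance) -> str:
    """Name the first period whose service level fails even at full capacity."""
    T = inst.n_periods
    total_capf = sum(inst.capf_treat[n.id] for n in inst.treat_sites)
    cum_supply = sum(inst.init_inventory(z.id) for z in inst.center_sites)
    cum_need = 0.0
    for t in range(T):
        intake = sum(inst.capd_center[z.id][t] for z in inst.center_sites)
        collect = sum(inst.capa_temp[s.id][t] for s in inst.temp_sites) + sum(
            inst.capa_perm[s.id][t] for s in inst.perm_sites
        )
        cum_supply += inst.beta * min(intake, collect)
        need = inst.lam * inst.transfusion_demand(t)
        cum_need += need
        if need > total_capf + 1e-9:
            return (
                f"period {t}: service level needs {need:.1f} units but total "
                f"treatment capacity is {total_capf:.1f}"
            )
        if cum_need > cum_supply + 1e-9:
            return (
                f"period {t}: cumulative service requirement {cum_need:.1f} units "
                f"exceeds maximum deliverable supply {cum_supply:.1f}"
            )
    return "no single-period capacity bound explains the infeasibility"


def solve_single_objective(
    inst: NetworkInstance, opts: SolveOptions | None = None
) -> Solution:
    """Solve the deterministic model under one objective.

    All three objective evaluations are populated on the returned solution
    regardless of which objective was optimized.
    """
    opts = opts or SolveOptions()
    diags = validate_instance(inst)
    if diags:
        raise ValueError("invalid instance: " + "; ".join(diags))
    if len(inst.scenarios) > 1:
        raise ValueError(
            "instance has multiple scenarios; use the scenario module or "
            "restrict_to_scenario first"
        )
    sys = assemble_constraints(inst, integral_vehicles=opts.integral_vehicles)
    sys.model.set_objective(
        _objective_coeffs(inst, opts.objective, opts.integral_vehicles)
    )
    status, values, _ = sys.model.solve(opts.mip_gap, opts.time_limit)
    if status != "optimal" or not values:
        sol = Solution(instance_id=inst.id, solver_status=status)
        if status == "infeasible":
            sol.infeasibility_hint = infeasibility_hint(inst)
        sol.solve_options = json.loads(opts.model_dump_json())
        return sol
    sol = _extract_solution(inst, values)
    sol.solver_status = "optimal"
    sol.solve_options = json.loads(opts.model_dump_json())
    sol.objective_cost = evaluate_cost(
        inst, sol, integral_vehicles=opts.integral_vehicles
    )
    ratio, units = evaluate_shortage(inst, sol)
    sol.objective_shortage_ratio = ratio
    sol.objective_shortage_units = units
    return sol


# ---------------------------------------------------------------------------
# objective evaluation (usable on any solution, solver-independent arithmetic)


def evaluate_cost(
    inst: NetworkInstance, sol: Solution, integral_vehicles: bool = False
) -> float:
    """Setup + transport + testing cost of a solution.

    Transport is per unit*km by default; with ``integral_vehicles`` it is
    per trip*km with trips = ceil(flow / vehicle_capacity).  Testing cost is
    charged per raw unit entering a blood center.
    """
    total = 0.0
    for s in inst.temp_sites:
        if not s.exists and sol.open_temp.get(s.id, False):
            total += s.setup_cost
    for s in inst.perm_sites:
        if not s.exists and sol.open_perm.get(s.id, False):
            total += s.setup_cost
    for s in inst.center_sites:
        if not s.exists and sol.open_center.get(s.id, False):
            total += s.setup_cost
    for s in inst.field_sites:
        if not s.exists and sol.open_field.get(s.id, False):
            total += s.setup_cost

    c = inst.unit_transport_cost

    def arc_cost(flow: float, dist: float) -> float:
        if flow <= 0:
            return 0.0
        if integral_vehicles:
            return math.ceil(flow / inst.vehicle_capacity - 1e-9) * dist * c
        return flow * dist * c

    tested = 0.0
    for a, table in list(sol.ship_temp.items()) + list(sol.ship_perm.items()):
        for z, flows in table.items():
            d = inst.distance(a, z)  # raises on missing distance
            for f in flows:
                total += arc_cost(f, d)
                tested += f
    for z, table in sol.deliver.items():
        for n, flows in table.items():
            d = inst.distance(z, n)
            for f in flows:
                total += arc_cost(f, d)
    total += inst.unit_test_cost * tested
    return total


def evaluate_shortage(
    inst: NetworkInstance, sol: Solution
) -> tuple[float, float]:
    """(sum over periods of shortage/demand ratio, total shortage units)."""
    ratio_sum = 0.0
    total = 0.0
    for t, ib in enumerate(sol.shortage):
        dem = inst.transfusion_demand(t)
        if dem <= 0:
            if ib > 1e-9:
                raise ValueError(
                    f"inconsistent solution: shortage {ib} in zero-demand period {t}"
                )
            continue
        ratio_sum += ib / dem
        total += ib
    return ratio_sum, total
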