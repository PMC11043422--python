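"""Solver-independent solution checking and brute-force ground-truth oracles.

The checker recomputes every constraint residual directly from instance
data and solution values; it shares no model-assembly code with the MILP
module.  The oracles enumerate all facility open-configurations of a tiny
instance and certify objective optima by network-flow computations on a
time-expanded network:

* shortage: augmenting-path max-flow (networkx), with the uniform testing
  pass-rate beta handled by measuring downstream requirements in raw
  (pre-testing) units — every capacity downstream of the testing layer is
  divided by beta and delivered units are beta * raw flow.  This rescaling
  is exact because beta multiplies every unit at exactly one layer, so a
  feasible raw flow of value v corresponds one-to-one to a feasible
  post-testing flow of value beta * v.
* cost: successive-shortest-path min-cost flow (hand-rolled on the residual
  graph; float capacities) meeting exactly the lambda service-level demand,
  which is cost-minimal because all unit costs are non-negative.

Per-period service-level feasibility is certified by max-flow with sink
capacities set to the lambda requirements: that flow saturates all sinks
iff every subset of periods can be covered simultaneously (max-flow/min-cut
over sink-side cuts), and a feasible requirement vector can always be
extended to a maximum total flow, so the lambda constraint never changes
the minimum total shortage when it is satisfiable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .instance import NetworkInstance, SiteKind
from .milp import InfeasibleError, Solution

TOL = 1e-6


@dataclass
class Violation:
    family: str
    indices: tuple
    magnitude: float
    tolerance: float = TOL

    def __str__(self) -> str:
        return f"{self.family}{list(self.indices)}: residual {self.magnitude:g}"


@dataclass
class CheckReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def families(self) -> set[str]:
        return {v.family for v in self.violations}

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "violations": [
                {
                    "family": v.family,
                    "indices": list(v.indices),
                    "magnitude": v.magnitude,
                    "tolerance": v.tolerance,
                }
                for v in self.violations
            ],
        }


# ---------------------------------------------------------------------------
# checker


def check_solution(
    inst: NetworkInstance, sol: Solution, tol: float = TOL
) -> CheckReport:
    """Evaluate every constraint family's residual directly from the data.

    Linkage families (eq2/4/8/9/10/11/15/17) are checked logically — any
    positive flow through a closed facility is a violation of that flow's
    magnitude — so the check does not depend on big-M values.  The
    destination-open family for existing treatment centers (the model's
    eq16 slot) has no content: those nodes are open by definition.
    """
    rep = CheckReport()

    def viol(family: str, idx: tuple, mag: float) -> None:
        if mag > tol:
            rep.violations.append(Violation(family, idx, mag, tol))

    T = inst.n_periods
    temps = inst.temp_sites
    perms = inst.perm_sites
    centers = inst.center_sites
    treats = inst.treat_sites

    def qt(i: str, z: str, t: int) -> float:
        return sol.ship_temp.get(i, {}).get(z, [0.0] * T)[t]

    def qc(u: str, z: str, t: int) -> float:
        return sol.ship_perm.get(u, {}).get(z, [0.0] * T)[t]

    def th(z: str, n: str, t: int) -> float:
        return sol.deliver.get(z, {}).get(n, [0.0] * T)[t]

    # nonnegativity over all flow-like quantities
    for name, table in (
        ("collected_temp", sol.collected_temp),
        ("collected_perm", sol.collected_perm),
        ("inventory", sol.inventory),
    ):
        for sid, row in table.items():
            for t, v in enumerate(row):
                viol("nonnegativity", (name, sid, t), -v)
    for name, table in (("ship_temp", sol.ship_temp), ("ship_perm", sol.ship_perm),
                        ("deliver", sol.deliver)):
        for a, sub in table.items():
            for b, row in sub.items():
                for t, v in enumerate(row):
                    viol("nonnegativity", (name, a, b, t), -v)
    for t, v in enumerate(sol.shortage):
        viol("nonnegativity", ("shortage", t), -v)

    # existing facilities must be open (binarity of fixed decisions)
    for s in inst.sites:
        if s.exists and not sol.is_open(s.id):
            viol("binarity", (s.id,), 1.0)

    for t in range(T):
        for s in temps:
            ch = sol.collected_temp.get(s.id, [0.0] * T)[t]
            viol("eq1", (s.id, t), ch - inst.capa_temp[s.id][t])
            if not sol.open_temp.get(s.id, s.exists):
                viol("eq2", (s.id, t), ch)
            shipped = sum(qt(s.id, z.id, t) for z in centers)
            viol("eq5", (s.id, t), abs(ch - shipped))
        for s in perms:
            bh = sol.collected_perm.get(s.id, [0.0] * T)[t]
            viol("eq3", (s.id, t), bh - inst.capa_perm[s.id][t])
            if not sol.open_perm.get(s.id, s.exists):
                viol("eq4", (s.id, t), bh)
            shipped = sum(qc(s.id, z.id, t) for z in centers)
            viol("eq6", (s.id, t), abs(bh - shipped))
        for z in centers:
            intake = sum(qt(s.id, z.id, t) for s in temps) + sum(
                qc(s.id, z.id, t) for s in perms
            )
            viol("eq7", (z.id, t), intake - inst.capd_center[z.id][t])
            opened = sol.open_center.get(z.id, z.exists)
            for s in temps:
                if not opened:
                    viol("eq8", (s.id, z.id, t), qt(s.id, z.id, t))
                if not sol.open_temp.get(s.id, s.exists):
                    viol("eq10", (s.id, z.id, t), qt(s.id, z.id, t))
            for s in perms:
                if not opened:
                    viol("eq9", (s.id, z.id, t), qc(s.id, z.id, t))
                if not sol.open_perm.get(s.id, s.exists):
                    viol("eq11", (s.id, z.id, t), qc(s.id, z.id, t))
            prev = (
                sol.inventory.get(z.id, [0.0] * T)[t - 1]
                if t > 0
                else inst.init_inventory(z.id)
            )
            delivered_from_z = sum(th(z.id, n.id, t) for n in treats)
            balance = (
                inst.beta * intake
                + prev
                - delivered_from_z
                - sol.inventory.get(z.id, [0.0] * T)[t]
            )
            viol("eq12", (z.id, t), abs(balance))
            for n in treats:
                if not opened:
                    viol("eq15", (z.id, n.id, t), th(z.id, n.id, t))
                if n.kind == SiteKind.field_hospital and not sol.open_field.get(
                    n.id, n.exists
                ):
                    viol("eq17", (z.id, n.id, t), th(z.id, n.id, t))
        for n in treats:
            received = sum(th(z.id, n.id, t) for z in centers)
            viol("eq13", (n.id, t), received - inst.capf_treat[n.id])
        dem = inst.transfusion_demand(t)
        delivered = sum(th(z.id, n.id, t) for z in centers for n in treats)
        ib = sol.shortage[t] if t < len(sol.shortage) else 0.0
        viol("eq14", (t,), abs(delivered + ib - dem))
        viol("eq18", (t,), inst.lam * dem - delivered)

    return rep


# ---------------------------------------------------------------------------
# configuration enumeration


def _tiny_guard(inst: NetworkInstance) -> None:
    for kind, cap in (
        (SiteKind.temporary_collection, 3),
        (SiteKind.permanent_facility, 3),
        (SiteKind.blood_center, 3),
        (SiteKind.treatment_center, 3),
        (SiteKind.field_hospital, 3),
    ):
        n = len(inst.sites_of(kind))
        if n > cap:
            raise ValueError(
                f"instance exceeds tiny bounds: {n} sites of kind {kind.value}"
            )
    if inst.n_periods > 4:
        raise ValueError("instance exceeds tiny bounds: more than 4 periods")
    n_cand = sum(1 for s in inst.sites if not s.exists)
    if 2**n_cand > 4096:
        raise ValueError("instance exceeds tiny bounds: > 4096 configurations")


def _configurations(inst: NetworkInstance):
    """Yield open-site sets: all existing sites plus every candidate subset."""
    always = [s.id for s in inst.sites if s.exists]
    cands = [
        s.id
        for s in inst.sites
        if not s.exists and s.kind != SiteKind.treatment_center
    ]
    for mask in itertools.product([False, True], repeat=len(cands)):
        chosen = [c for c, m in zip(cands, mask) if m]
        yield frozenset(always) | frozenset(chosen)


# ---------------------------------------------------------------------------
# time-expanded flow network (raw, pre-testing units)


def _flow_graph(
    inst: NetworkInstance,
    open_sites: frozenset[str],
    sink_caps: list[float],
) -> nx.DiGraph:
    g = nx.DiGraph()
    beta = inst.beta
    T = inst.n_periods
    big = sum(sink_caps) + sum(
        sum(row) for row in inst.capa_temp.values()
    ) + sum(sum(row) for row in inst.capa_perm.values()) + 1.0
    for t in range(T):
        for s in inst.temp_sites:
            if s.id in open_sites:
                g.add_edge("SRC", ("coll", s.id, t), capacity=inst.capa_temp[s.id][t])
        for s in inst.perm_sites:
            if s.id in open_sites:
                g.add_edge("SRC", ("coll", s.id, t), capacity=inst.capa_perm[s.id][t])
        for z in inst.center_sites:
            if z.id not in open_sites:
                continue
            g.add_edge(("cin", z.id, t), ("cout", z.id, t),
                       capacity=inst.capd_center[z.id][t])
            for s in inst.temp_sites + inst.perm_sites:
                if s.id in open_sites:
                    g.add_edge(("coll", s.id, t), ("cin", z.id, t), capacity=big)
            if t + 1 < T:
                g.add_edge(("cout", z.id, t), ("cout", z.id, t + 1), capacity=big)
            if t == 0 and inst.init_inventory(z.id) > 0:
                g.add_edge("SRC", ("cout", z.id, 0),
                           capacity=inst.init_inventory(z.id) / beta)
            for n in inst.treat_sites:
                if n.kind == SiteKind.field_hospital and n.id not in open_sites:
                    continue
                g.add_edge(("cout", z.id, t), ("trt", n.id, t), capacity=big)
        for n in inst.treat_sites:
            if n.kind == SiteKind.field_hospital and n.id not in open_sites:
                continue
            g.add_edge(("trt", n.id, t), ("dem", t),
                       capacity=inst.capf_treat[n.id] / beta)
        g.add_edge(("dem", t), "SNK", capacity=sink_caps[t])
    return g


def _max_deliverable_raw(
    inst: NetworkInstance, open_sites: frozenset[str], sink_caps: list[float]
) -> float:
    g = _flow_graph(inst, open_sites, sink_caps)
    if "SRC" not in g or "SNK" not in g:
        return 0.0
    value, _ = nx.maximum_flow(g, "SRC", "SNK")
    return value


def _lambda_feasible(inst: NetworkInstance, open_sites: frozenset[str]) -> bool:
    req = [
        inst.lam * inst.transfusion_demand(t) / inst.beta
        for t in range(inst.n_periods)
    ]
    total = sum(req)
    if total <= 0:
        return True
    return _max_deliverable_raw(inst, open_sites, req) >= total - TOL


def oracle_min_shortage(inst: NetworkInstance) -> float:
    """Minimum total shortage units over all facility configurations.

    Raises :class:`InfeasibleError` when no configuration satisfies the
    lambda service level, and ValueError past tiny bounds.
    """
    _tiny_guard(inst)
    if len(inst.scenarios) > 1:
        raise ValueError("oracle operates on single-scenario instances")
    T = inst.n_periods
    demand_units = [inst.transfusion_demand(t) for t in range(T)]
    total_demand = sum(demand_units)
    best: Optional[float] = None
    for cfg in _configurations(inst):
        if not _lambda_feasible(inst, cfg):
            continue
        raw = _max_deliverable_raw(
            inst, cfg, [d / inst.beta for d in demand_units]
        )
        shortage = max(0.0, total_demand - inst.beta * raw)
        if best is None or shortage < best:
            best = shortage
        if best <= TOL:
            return 0.0
    if best is None:
        raise InfeasibleError(
            "no facility configuration satisfies the service level"
        )
    return best


# ---------------------------------------------------------------------------
# successive-shortest-path min-cost flow (float capacities, non-negative costs)


def _ssp_min_cost(
    nodes: list, arcs: list[tuple], source, sink, target_flow: float
) -> Optional[float]:
    """Send target_flow units source->sink at min cost; None if short.

    arcs: (u, v, capacity, unit_cost).  Bellman-Ford shortest augmenting
    paths on the residual graph; exact for the tiny graphs used here.
    """
    idx = {n: k for k, n in enumerate(nodes)}
    # residual arc lists: cap, cost, and a pointer to the reverse arc
    head: list[int] = []
    tail: list[int] = []
    cap: list[float] = []
    cost: list[float] = []
    adj: list[list[int]] = [[] for _ in nodes]

    def add(u: int, v: int, c: float, w: float) -> None:
        adj[u].append(len(head))
        tail.append(u)
        head.append(v)
        cap.append(c)
        cost.append(w)
        adj[v].append(len(head))
        tail.append(v)
        head.append(u)
        cap.append(0.0)
        cost.append(-w)

    for u, v, c, w in arcs:
        if c > 0:
            add(idx[u], idx[v], c, w)

    s, t = idx[source], idx[sink]
    sent = 0.0
    total_cost = 0.0
    n = len(nodes)
    while sent < target_flow - TOL:
        dist = [math.inf] * n
        parent_arc = [-1] * n
        dist[s] = 0.0
        for _ in range(n):  # Bellman-Ford
            changed = False
            for a in range(len(head)):
                if cap[a] > TOL:
                    u, v = tail[a], head[a]
                    nd = dist[u] + cost[a]
                    if nd < dist[v] - 1e-12:
                        dist[v] = nd
                        parent_arc[v] = a
                        changed = True
            if not changed:
                break
        if not math.isfinite(dist[t]):
            return None
        # bottleneck along the path
        push = target_flow - sent
        v = t
        while v != s:
            a = parent_arc[v]
            push = min(push, cap[a])
            v = tail[a]
        v = t
        while v != s:
            a = parent_arc[v]
            cap[a] -= push
            cap[a ^ 1] += push
            v = tail[a]
        sent += push
        total_cost += push * dist[t]
    return total_cost


def oracle_min_cost(
    inst: NetworkInstance, require_lambda: bool = True
) -> float:
    """Minimum setup + flow cost over all lambda-feasible configurations.

    Per configuration the remaining problem is a min-cost flow meeting
    exactly the per-period service-level requirement (delivering more than
    the requirement can only add cost).  Raises :class:`InfeasibleError`
    when no configuration is feasible.
    """
    _tiny_guard(inst)
    if len(inst.scenarios) > 1:
        raise ValueError("oracle operates on single-scenario instances")
    T = inst.n_periods
    beta = inst.beta
    c = inst.unit_transport_cost
    lam = inst.lam if require_lambda else 0.0
    req_raw = [lam * inst.transfusion_demand(t) / beta for t in range(T)]
    target = sum(req_raw)
    big = sum(
        sum(row) for row in inst.capa_temp.values()
    ) + sum(sum(row) for row in inst.capa_perm.values()) + target + 1.0

    best: Optional[float] = None
    for cfg in _configurations(inst):
        setup = sum(
            s.setup_cost for s in inst.sites if not s.exists and s.id in cfg
        )
        if best is not None and setup >= best:
            continue
        nodes: list = ["SRC", "SNK"]
        arcs: list[tuple] = []
        open_centers = [z for z in inst.center_sites if z.id in cfg]
        open_colls = [
            s for s in inst.temp_sites + inst.perm_sites if s.id in cfg
        ]
        open_treats = [
            n
            for n in inst.treat_sites
            if n.kind != SiteKind.field_hospital or n.id in cfg
        ]
        for t in range(T):
            for s in open_colls:
                nodes.append(("coll", s.id, t))
                capr = (
                    inst.capa_temp[s.id][t]
                    if s.kind == SiteKind.temporary_collection
                    else inst.capa_perm[s.id][t]
                )
                arcs.append(("SRC", ("coll", s.id, t), capr, 0.0))
            for z in open_centers:
                nodes.append(("cin", z.id, t))
                nodes.append(("cout", z.id, t))
                # testing cost charged per raw unit crossing the intake
                arcs.append(
                    (("cin", z.id, t), ("cout", z.id, t),
                     inst.capd_center[z.id][t], inst.unit_test_cost)
                )
                for s in open_colls:
                    arcs.append(
                        (("coll", s.id, t), ("cin", z.id, t), big,
                         inst.distance(s.id, z.id) * c)
                    )
                if t > 0:
                    arcs.append(
                        (("cout", z.id, t - 1), ("cout", z.id, t), big, 0.0)
                    )
                if t == 0 and inst.init_inventory(z.id) > 0:
                    arcs.append(
                        ("SRC", ("cout", z.id, 0),
                         inst.init_inventory(z.id) / beta, 0.0)
                    )
            for n in open_treats:
                nodes.append(("trt", n.id, t))
                for z in open_centers:
                    # delivery cost is charged on post-testing units
                    arcs.append(
                        (("cout", z.id, t), ("trt", n.id, t), big,
                         beta * inst.distance(z.id, n.id) * c)
                    )
            nodes.append(("dem", t))
            for n in open_treats:
                arcs.append(
                    (("trt", n.id, t), ("dem", t),
                     inst.capf_treat[n.id] / beta, 0.0)
                )
            arcs.append((("dem", t), "SNK", req_raw[t], 0.0))
        flow_cost = (
            0.0
            if target <= TOL
            else _ssp_min_cost(nodes, arcs, "SRC", "SNK", target)
        )
        if flow_cost is None:
            continue
        total = setup + flow_cost
        if best is None or total < best:
            best = total
    if best is None:
        raise InfeasibleError(
            "no facility configuration satisfies the service level"
        )
    return best


# ---------------------------------------------------------------------------
# cross-validation driver


def compare_solver_to_oracle(seeds: list[int], dims: Optional[dict] = None) -> dict:
    """Solve both objectives on tiny instances and compare with the oracles.

    Returns {"n": ..., "mismatches": [...], "infeasible_agreements": k}.
    A mismatch records the seed, the objective and both values.
    """
    from .milp import SolveOptions, solve_single_objective
    from .synth import generate_tiny

    mismatches = []
    infeasible_agree = 0
    for seed in seeds:
        inst = generate_tiny(seed, dims)
        try:
            oracle_short = oracle_min_shortage(inst)
        except InfeasibleError:
            oracle_short = None
        try:
            oracle_cost = oracle_min_cost(inst)
        except InfeasibleError:
            oracle_cost = None

        sol_s = solve_single_objective(
            inst, SolveOptions(objective="shortage_units")
        )
        sol_c = solve_single_objective(inst, SolveOptions(objective="cost"))

        if oracle_short is None or oracle_cost is None:
            if sol_s.solver_status == "infeasible" and sol_c.solver_status == "infeasible":
                infeasible_agree += 1
            else:
                mismatches.append(
                    {"seed": seed, "objective": "feasibility",
                     "oracle": "infeasible",
                     "solver": (sol_s.solver_status, sol_c.solver_status)}
                )
            continue
        if sol_s.solver_status != "optimal" or sol_c.solver_status != "optimal":
            mismatches.append(
                {"seed": seed, "objective": "feasibility", "oracle": "feasible",
                 "solver": (sol_s.solver_status, sol_c.solver_status)}
            )
            continue
        if abs(sol_s.objective_shortage_units - oracle_short) > 1e-6:
            mismatches.append(
                {"seed": seed, "objective": "shortage_units",
                 "solver": sol_s.objective_shortage_units, "oracle": oracle_short}
            )
        denom = max(1.0, abs(oracle_cost))
        if abs(sol_c.objective_cost - oracle_cost) / denom > 1e-6:
            mismatches.append(
                {"seed": seed, "objective": "cost",
                 "solver": sol_c.objective_cost, "oracle": oracle_cost}
            )
    return {
        "n": len(seeds),
        "mismatches": mismatches,
        "infeasible_agreements": infeasible_agree,
    }
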