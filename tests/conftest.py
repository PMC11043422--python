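"""Shared builders: hand-sized instances with closed-form optima."""

from __future__ import annotations

import copy

import pytest

from bloodnet.instance import FacilitySite, NetworkInstance, ScenarioSpec, SiteKind
from bloodnet.milp import Solution


def chain_instance(
    demand: float = 10.0,
    lam: float = 0.5,
    capa: float = 10.0,
    capd: float = 10.0,
    capf: float = 10.0,
    n_periods: int = 1,
    setup_temp: float = 1000.0,
    alpha: float = 0.8,
    beta: float = 0.8,
) -> NetworkInstance:
    """Single-path chain: 1 temporary site -> 1 blood center -> 1 treatment center.

    With capa = capd = capf = 10, demand 10, alpha = beta = 0.8 the unique
    path delivers beta*10 = 8 = alpha*10 units, so the shortage optimum is 0;
    at demand 20 it is alpha*20 - 8 = 8 units (ratio 0.5).
    """
    inst = NetworkInstance(
        id="chain",
        sites=[
            FacilitySite(id="t1", kind=SiteKind.temporary_collection,
                         exists=False, setup_cost=setup_temp),
            FacilitySite(id="c1", kind=SiteKind.blood_center, exists=True),
            FacilitySite(id="n1", kind=SiteKind.treatment_center, exists=True),
        ],
        periods=[24.0] * n_periods,
        alpha=alpha,
        beta=beta,
        lam=lam,
        vehicle_capacity=100.0,
        unit_transport_cost=5.0,
        unit_test_cost=7.0,
    )
    inst.capa_temp["t1"] = [capa] * n_periods
    inst.capd_center["c1"] = [capd] * n_periods
    inst.capf_treat["n1"] = capf
    inst.demand = [demand] * n_periods
    inst.dist_coll_center["t1"] = {"c1": 2.0}
    inst.dist_center_treat["c1"] = {"n1": 3.0}
    return inst


def tradeoff_instance(
    n_scenarios: int = 1,
    setup_center2: float = 50_000.0,
) -> NetworkInstance:
    """Cost/shortage trade-off: a pricey second blood center halves the shortage.

    One candidate temporary site (capa 10) feeds an existing center c1
    (intake 5) and, if built, a candidate center c2 (intake 5, expensive).
    Demand 10, alpha = beta = 0.8: with c1 only at most beta*5 = 4 of the
    alpha*10 = 8 required units arrive (shortage 4); building c2 doubles
    intake and eliminates the shortage.
    """
    scenarios = [ScenarioSpec(id="s1", probability=1.0)]
    if n_scenarios == 2:
        scenarios = [
            ScenarioSpec(id="s1", probability=0.4, demand_multiplier=1.0),
            ScenarioSpec(id="s2", probability=0.6, demand_multiplier=1.5,
                         setup_cost_multiplier=1.25),
        ]
    inst = NetworkInstance(
        id="tradeoff",
        sites=[
            FacilitySite(id="t1", kind=SiteKind.temporary_collection,
                         exists=False, setup_cost=1000.0),
            FacilitySite(id="c1", kind=SiteKind.blood_center, exists=True),
            FacilitySite(id="c2", kind=SiteKind.blood_center, exists=False,
                         setup_cost=setup_center2),
            FacilitySite(id="n1", kind=SiteKind.treatment_center, exists=True),
        ],
        periods=[24.0],
        scenarios=scenarios,
        alpha=0.8,
        beta=0.8,
        lam=0.25,
        vehicle_capacity=100.0,
        unit_transport_cost=5.0,
        unit_test_cost=7.0,
    )
    inst.capa_temp["t1"] = [10.0]
    inst.capd_center["c1"] = [5.0]
    inst.capd_center["c2"] = [5.0]
    inst.capf_treat["n1"] = 100.0
    inst.demand = [10.0]
    inst.dist_coll_center["t1"] = {"c1": 2.0, "c2": 4.0}
    inst.dist_center_treat["c1"] = {"n1": 3.0}
    inst.dist_center_treat["c2"] = {"n1": 1.0}
    return inst


def rich_tiny_instance() -> NetworkInstance:
    """Every site kind with a candidate, for exercising all linkage families."""
    inst = NetworkInstance(
        id="rich",
        sites=[
            FacilitySite(id="t1", kind=SiteKind.temporary_collection,
                         exists=False, setup_cost=1000.0),
            FacilitySite(id="p1", kind=SiteKind.permanent_facility,
                         exists=False, setup_cost=2000.0),
            FacilitySite(id="c1", kind=SiteKind.blood_center,
                         exists=False, setup_cost=5000.0),
            FacilitySite(id="n1", kind=SiteKind.treatment_center, exists=True),
            FacilitySite(id="f1", kind=SiteKind.field_hospital,
                         exists=False, setup_cost=3000.0),
        ],
        periods=[24.0, 48.0],
        alpha=0.8,
        beta=0.8,
        lam=0.5,
        vehicle_capacity=100.0,
        unit_transport_cost=5.0,
        unit_test_cost=7.0,
    )
    inst.capa_temp["t1"] = [10.0, 10.0]
    inst.capa_perm["p1"] = [10.0, 10.0]
    inst.capd_center["c1"] = [20.0, 20.0]
    inst.capf_treat["n1"] = 10.0
    inst.capf_treat["f1"] = 10.0
    inst.demand = [10.0, 10.0]
    inst.dist_coll_center["t1"] = {"c1": 2.0}
    inst.dist_coll_center["p1"] = {"c1": 3.0}
    inst.dist_center_treat["c1"] = {"n1": 3.0, "f1": 1.0}
    return inst


def feasible_rich_solution() -> tuple[NetworkInstance, Solution]:
    """A hand-built feasible solution on the rich instance (verified by tests).

    Each period: collect 10 at t1 and 6.25 at p1, intake 16.25 raw at c1,
    beta*16.25 = 13 usable; deliver 8 (= alpha*10) split 5 to n1 and 3 to f1,
    store 5 at c1; period 2 delivers from fresh units again, inventory 10.
    """
    inst = rich_tiny_instance()
    sol = Solution(
        instance_id=inst.id,
        open_temp={"t1": True},
        open_perm={"p1": True},
        open_center={"c1": True},
        open_field={"f1": True},
        collected_temp={"t1": [10.0, 10.0]},
        collected_perm={"p1": [6.25, 6.25]},
        ship_temp={"t1": {"c1": [10.0, 10.0]}},
        ship_perm={"p1": {"c1": [6.25, 6.25]}},
        deliver={"c1": {"n1": [5.0, 5.0], "f1": [3.0, 3.0]}},
        inventory={"c1": [5.0, 10.0]},
        shortage=[0.0, 0.0],
    )
    return inst, copy.deepcopy(sol)


# Single-constraint mutations: (family, expected magnitude, mutator).
# Logically entailed co-flags in other families are allowed; the targeted
# family must be present with the stated residual.
def mutation_fixtures() -> list[tuple[str, float, callable]]:
    def m(fn):
        return fn

    return [
        ("eq1", 5.0, m(lambda s: s.collected_temp["t1"].__setitem__(0, 15.0))),
        ("eq2", 10.0, m(lambda s: s.open_temp.__setitem__("t1", False))),
        ("eq3", 3.75, m(lambda s: s.collected_perm["p1"].__setitem__(0, 13.75))),
        ("eq4", 6.25, m(lambda s: s.open_perm.__setitem__("p1", False))),
        ("eq5", 2.0, m(lambda s: s.collected_temp["t1"].__setitem__(0, 8.0))),
        ("eq6", 1.25, m(lambda s: s.collected_perm["p1"].__setitem__(0, 5.0))),
        # intake 17.75 + 6.25 = 24 raw against the center cap of 20
        ("eq7", 4.0, m(lambda s: (
            s.ship_temp["t1"]["c1"].__setitem__(0, 17.75),
            s.collected_temp["t1"].__setitem__(0, 17.75),
        ))),
        ("eq8", 10.0, m(lambda s: s.open_center.__setitem__("c1", False))),
        ("eq9", 6.25, m(lambda s: s.open_center.__setitem__("c1", False))),
        ("eq10", 10.0, m(lambda s: s.open_temp.__setitem__("t1", False))),
        ("eq11", 6.25, m(lambda s: s.open_perm.__setitem__("p1", False))),
        ("eq12", 1.0, m(lambda s: s.inventory["c1"].__setitem__(1, 11.0))),
        ("eq13", 2.0, m(lambda s: (
            s.deliver["c1"]["n1"].__setitem__(0, 12.0),
            s.shortage.__setitem__(0, 0.0),
        ))),
        ("eq14", 2.0, m(lambda s: s.shortage.__setitem__(0, 2.0))),
        ("eq15", 5.0, m(lambda s: s.open_center.__setitem__("c1", False))),
        ("eq17", 3.0, m(lambda s: s.open_field.__setitem__("f1", False))),
        # deliver only 3 of the lam*alpha*Dem = 4 required units in period 1
        ("eq18", 1.0, m(lambda s: (
            s.deliver["c1"]["n1"].__setitem__(0, 0.0),
            s.shortage.__setitem__(0, 5.0),
            s.inventory["c1"].__setitem__(0, 10.0),
            s.inventory["c1"].__setitem__(1, 20.0),
        ))),
        ("nonnegativity", 1.0, m(lambda s: s.shortage.__setitem__(1, -1.0))),
    ]


@pytest.fixture(scope="session")
def kermanshah_instance():
    from bloodnet.synth import generate_instance, kermanshah_profile

    return generate_instance(kermanshah_profile(), 1)
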