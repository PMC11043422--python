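"""Seeded generators of valid problem instances.

Two entry points:

* :func:`kermanshah_profile` / :func:`generate_instance` — a realistic
  earthquake-response profile shaped like the Kermanshah case: 8 candidate
  temporary collection sites, 5 permanent facilities (2 pre-existing),
  3 blood-center sites (1 pre-existing), 5 existing treatment centers and
  5 candidate field hospitals, 4 response periods (24 h / 48 h / next 72 h /
  following week) and 3 severity scenarios with probabilities
  0.15 / 0.35 / 0.5 and demand increasing with severity.

* :func:`generate_tiny` — integer-data instances small enough for
  exhaustive enumeration of facility configurations (<= 4096) so that
  brute-force flow oracles can certify MILP optima.

All draws come from ``numpy.random.default_rng(seed)`` in a fixed order, so
(profile, seed) fully determines the instance.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .instance import (
    FacilitySite,
    NetworkInstance,
    ScenarioSpec,
    SiteKind,
)

Range = tuple[float, float]


class GeneratorProfile(BaseModel):
    """Sampling ranges and fixed parameters for instance generation."""

    model_config = ConfigDict(frozen=True)

    name: str = "profile"
    n_temp: int = 8
    n_perm: int = 5
    n_perm_existing: int = 2
    n_center: int = 3
    n_center_existing: int = 1
    n_treat_existing: int = 5
    n_field: int = 5
    n_periods: int = 4
    period_hours: tuple[float, ...] = (24.0, 48.0, 72.0, 168.0)
    scenarios: tuple[ScenarioSpec, ...] = ()
    demand_base: Range = (3000.0, 6000.0)  # persons, period 1
    demand_period_shape: tuple[float, ...] = (1.0, 0.7, 0.45, 0.25)
    distance_range: Range = (1.0, 30.0)  # km
    capa_temp_range: Range = (200.0, 400.0)  # units / period
    capa_perm_range: Range = (400.0, 800.0)
    capd_center_range: Range = (2000.0, 5000.0)
    capf_treat_range: Range = (1500.0, 4000.0)
    setup_temp_range: Range = (2e6, 5e6)  # currency
    setup_perm_range: Range = (2e8, 5e8)
    setup_center_range: Range = (1e9, 1e9)
    setup_field_range: Range = (3e8, 7e8)
    alpha: float = 0.8
    beta: float = 0.8
    lam: float = 0.7
    vehicle_capacity: float = 100.0
    unit_transport_cost: float = 5000.0
    unit_test_cost: float = 5000.0
    units_per_patient: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorProfile":
        for fname in (
            "demand_base", "distance_range", "capa_temp_range", "capa_perm_range",
            "capd_center_range", "capf_treat_range", "setup_temp_range",
            "setup_perm_range", "setup_center_range", "setup_field_range",
        ):
            lo, hi = getattr(self, fname)
            if lo < 0 or hi < lo:
                raise ValueError(f"{fname}: need 0 <= low <= high, got ({lo}, {hi})")
        if len(self.demand_period_shape) != self.n_periods:
            raise ValueError("demand_period_shape length must equal n_periods")
        if self.scenarios:
            psum = sum(s.probability for s in self.scenarios)
            if abs(psum - 1.0) > 1e-9:
                raise ValueError(f"scenario probabilities sum to {psum}, not 1")
        return self


def kermanshah_profile() -> GeneratorProfile:
    """The earthquake-case profile: 8/5/3/5 sites, 4 periods, 3 scenarios.

    Scenario probabilities are (0.15, 0.35, 0.5) with severity (and demand)
    increasing; alpha = beta = 0.8, lambda = 0.7, vehicle capacity 100,
    transport 5,000 per unit*km, testing 5,000 per unit, blood-center setup
    1e9 (all in Rials).
    """
    return GeneratorProfile(
        name="kermanshah",
        scenarios=(
            ScenarioSpec(
                id="s1", probability=0.15, demand_multiplier=0.8,
                setup_cost_multiplier=1.0, capacity_multiplier=1.0,
            ),
            ScenarioSpec(
                id="s2", probability=0.35, demand_multiplier=1.0,
                setup_cost_multiplier=1.1, capacity_multiplier=1.05,
            ),
            ScenarioSpec(
                id="s3", probability=0.5, demand_multiplier=1.3,
                setup_cost_multiplier=1.25, capacity_multiplier=1.1,
            ),
        ),
    )


def _draw(rng: np.random.Generator, r: Range, round_to: float = 1.0) -> float:
    v = rng.uniform(r[0], r[1])
    if round_to > 0:
        v = round(v / round_to) * round_to
    return float(v)


def generate_instance(profile: GeneratorProfile, seed: int) -> NetworkInstance:
    """Draw a valid instance from the profile; deterministic in (profile, seed)."""
    rng = np.random.default_rng(seed)
    sites: list[FacilitySite] = []
    for k in range(profile.n_temp):
        sites.append(
            FacilitySite(
                id=f"t{k + 1}", kind=SiteKind.temporary_collection, exists=False,
                setup_cost=_draw(rng, profile.setup_temp_range, 1000.0),
            )
        )
    for k in range(profile.n_perm):
        exists = k < profile.n_perm_existing
        sites.append(
            FacilitySite(
                id=f"p{k + 1}", kind=SiteKind.permanent_facility, exists=exists,
                setup_cost=0.0 if exists else _draw(rng, profile.setup_perm_range, 1e6),
            )
        )
    for k in range(profile.n_center):
        exists = k < profile.n_center_existing
        sites.append(
            FacilitySite(
                id=f"c{k + 1}", kind=SiteKind.blood_center, exists=exists,
                setup_cost=0.0 if exists else _draw(rng, profile.setup_center_range, 1e6),
            )
        )
    for k in range(profile.n_treat_existing):
        sites.append(
            FacilitySite(
                id=f"n{k + 1}", kind=SiteKind.treatment_center, exists=True,
                setup_cost=0.0,
            )
        )
    for k in range(profile.n_field):
        sites.append(
            FacilitySite(
                id=f"f{k + 1}", kind=SiteKind.field_hospital, exists=False,
                setup_cost=_draw(rng, profile.setup_field_range, 1e6),
            )
        )

    T = profile.n_periods
    inst = NetworkInstance(
        id=f"{profile.name}-{seed}",
        sites=sites,
        periods=list(profile.period_hours),
        scenarios=list(profile.scenarios)
        or [ScenarioSpec(id="s1", probability=1.0)],
        alpha=profile.alpha,
        beta=profile.beta,
        lam=profile.lam,
        vehicle_capacity=profile.vehicle_capacity,
        unit_transport_cost=profile.unit_transport_cost,
        unit_test_cost=profile.unit_test_cost,
        units_per_patient=profile.units_per_patient,
    )
    for s in inst.temp_sites:
        inst.capa_temp[s.id] = [
            _draw(rng, profile.capa_temp_range, 10.0) for _ in range(T)
        ]
    for s in inst.perm_sites:
        inst.capa_perm[s.id] = [
            _draw(rng, profile.capa_perm_range, 10.0) for _ in range(T)
        ]
    for s in inst.center_sites:
        inst.capd_center[s.id] = [
            _draw(rng, profile.capd_center_range, 10.0) for _ in range(T)
        ]
    for s in inst.treat_sites:
        inst.capf_treat[s.id] = _draw(rng, profile.capf_treat_range, 10.0)

    base = _draw(rng, profile.demand_base, 10.0)
    inst.demand = [
        float(round(base * m)) for m in profile.demand_period_shape
    ]

    for a in inst.temp_sites + inst.perm_sites:
        inst.dist_coll_center[a.id] = {
            z.id: _draw(rng, profile.distance_range, 0.1)
            for z in inst.center_sites
        }
    for z in inst.center_sites:
        inst.dist_center_treat[z.id] = {
            n.id: _draw(rng, profile.distance_range, 0.1)
            for n in inst.treat_sites
        }
    return inst


TINY_DEFAULT_DIMS = {
    "n_temp": 1, "n_perm": 1, "n_center": 1, "n_treat": 1, "n_field": 1,
    "n_periods": 1, "n_scenarios": 1,
}


def generate_tiny(seed: int, dims: Optional[dict] = None) -> NetworkInstance:
    """Integer-data instance small enough for brute-force oracles.

    Bounds: each site count <= 3, periods <= 2, scenarios <= 2; capacities
    are integers <= 20 and demands integers, so exhaustive configuration
    enumeration plus flow search is sub-second.
    """
    d = dict(TINY_DEFAULT_DIMS)
    d.update(dims or {})
    for key in ("n_temp", "n_perm", "n_center", "n_treat", "n_field"):
        if not (0 <= d[key] <= 3):
            raise ValueError(f"tiny bound violated: {key}={d[key]} (max 3)")
    if not (1 <= d["n_periods"] <= 2):
        raise ValueError("tiny bound violated: n_periods must be 1 or 2")
    if not (1 <= d["n_scenarios"] <= 2):
        raise ValueError("tiny bound violated: n_scenarios must be 1 or 2")
    if d["n_center"] < 1 or d["n_treat"] + d["n_field"] < 1:
        raise ValueError("tiny instance needs at least one center and one treatment node")

    rng = np.random.default_rng(seed)
    T = d["n_periods"]
    sites: list[FacilitySite] = []
    for k in range(d["n_temp"]):
        sites.append(FacilitySite(
            id=f"t{k + 1}", kind=SiteKind.temporary_collection, exists=False,
            setup_cost=float(rng.integers(1, 10) * 1000),
        ))
    for k in range(d["n_perm"]):
        exists = bool(rng.random() < 0.5)
        sites.append(FacilitySite(
            id=f"p{k + 1}", kind=SiteKind.permanent_facility, exists=exists,
            setup_cost=0.0 if exists else float(rng.integers(1, 10) * 1000),
        ))
    for k in range(d["n_center"]):
        exists = bool(rng.random() < 0.5)
        sites.append(FacilitySite(
            id=f"c{k + 1}", kind=SiteKind.blood_center, exists=exists,
            setup_cost=0.0 if exists else float(rng.integers(2, 20) * 1000),
        ))
    for k in range(d["n_treat"]):
        sites.append(FacilitySite(
            id=f"n{k + 1}", kind=SiteKind.treatment_center, exists=True,
        ))
    for k in range(d["n_field"]):
        sites.append(FacilitySite(
            id=f"f{k + 1}", kind=SiteKind.field_hospital, exists=False,
            setup_cost=float(rng.integers(1, 15) * 1000),
        ))

    scenarios = [ScenarioSpec(id="s1", probability=1.0)]
    if d["n_scenarios"] == 2:
        scenarios = [
            ScenarioSpec(id="s1", probability=0.5, demand_multiplier=1.0),
            ScenarioSpec(
                id="s2", probability=0.5, demand_multiplier=1.5,
                setup_cost_multiplier=1.2,
            ),
        ]

    inst = NetworkInstance(
        id=f"tiny-{seed}",
        sites=sites,
        periods=[24.0, 48.0][:T],
        scenarios=scenarios,
        alpha=0.8,
        beta=0.8,
        lam=0.5,
        vehicle_capacity=10.0,
        unit_transport_cost=5.0,
        unit_test_cost=7.0,
    )
    for s in inst.temp_sites:
        inst.capa_temp[s.id] = [float(rng.integers(2, 21)) for _ in range(T)]
    for s in inst.perm_sites:
        inst.capa_perm[s.id] = [float(rng.integers(2, 21)) for _ in range(T)]
    for s in inst.center_sites:
        inst.capd_center[s.id] = [float(rng.integers(5, 21)) for _ in range(T)]
    for s in inst.treat_sites:
        inst.capf_treat[s.id] = float(rng.integers(5, 21))
    inst.demand = [float(rng.integers(2, 16)) for _ in range(T)]
    for a in inst.temp_sites + inst.perm_sites:
        inst.dist_coll_center[a.id] = {
            z.id: float(rng.integers(1, 11)) for z in inst.center_sites
        }
    for z in inst.center_sites:
        inst.dist_center_treat[z.id] = {
            n.id: float(rng.integers(1, 11)) for n in inst.treat_sites
        }
    return inst
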