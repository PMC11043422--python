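"""Problem-instance data model, validation and file I/O.

A :class:`NetworkInstance` describes one post-disaster blood supply chain
design problem: candidate and existing facility sites in four classes
(temporary collection points, permanent collection/treatment facilities,
blood centers, field hospitals plus existing treatment centers), per-period
capacities, per-period demand in injured persons, inter-layer distance
matrices, unit costs, and the scalar parameters

* ``alpha`` — fraction of injured persons requiring a transfusion,
* ``beta``  — fraction of collected blood that survives testing/processing,
* ``lam``   — minimum per-period service level on transfusion demand,

together with a discrete scenario set (probability + multipliers on demand,
temporary-facility setup cost and capacities).

Instances serialize to a single JSON document with canonical key order;
the two distance matrices and the base demand vector may alternatively be
supplied as CSV sidecar files referenced from the JSON.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

PROB_TOL = 1e-9


class SiteKind(str, Enum):
    temporary_collection = "temporary_collection"
    permanent_facility = "permanent_facility"
    blood_center = "blood_center"
    treatment_center = "treatment_center"
    field_hospital = "field_hospital"


class FacilitySite(BaseModel):
    """One facility site: its class, candidate/existing status and setup cost."""

    model_config = ConfigDict(frozen=True)

    id: str
    kind: SiteKind
    exists: bool = False
    setup_cost: float = 0.0
    x: Optional[float] = None
    y: Optional[float] = None

    @model_validator(mode="after")
    def _non_negative_setup(self) -> "FacilitySite":
        if self.setup_cost < 0:
            raise ValueError(f"site {self.id}: setup_cost must be >= 0")
        return self


class ScenarioSpec(BaseModel):
    """A discrete scenario: probability plus multipliers applied to the base data."""

    model_config = ConfigDict(frozen=True)

    id: str
    probability: float
    demand_multiplier: float = 1.0
    setup_cost_multiplier: float = 1.0
    capacity_multiplier: float = 1.0

    @model_validator(mode="after")
    def _ranges(self) -> "ScenarioSpec":
        if not (0 < self.probability <= 1):
            raise ValueError(f"scenario {self.id}: probability must be in (0, 1]")
        if self.demand_multiplier < 0 or self.setup_cost_multiplier < 0:
            raise ValueError(f"scenario {self.id}: multipliers must be >= 0")
        if self.capacity_multiplier <= 0:
            raise ValueError(f"scenario {self.id}: capacity_multiplier must be > 0")
        return self


class NetworkInstance(BaseModel):
    """Full problem data for one network design instance.

    Site-indexed tables are keyed by site id; period-indexed vectors are
    plain lists aligned with ``periods``.  Demand is in injured persons per
    period; transfusion demand in blood units is
    ``alpha * units_per_patient * demand``.
    """

    model_config = ConfigDict(frozen=False)

    id: str = "instance"
    sites: list[FacilitySite]
    periods: list[float] = Field(default_factory=lambda: [24.0, 48.0, 72.0, 168.0])
    scenarios: list[ScenarioSpec] = Field(
        default_factory=lambda: [ScenarioSpec(id="s1", probability=1.0)]
    )
    # capacities, blood units / period
    capa_temp: dict[str, list[float]] = Field(default_factory=dict)
    capa_perm: dict[str, list[float]] = Field(default_factory=dict)
    capd_center: dict[str, list[float]] = Field(default_factory=dict)
    capf_treat: dict[str, float] = Field(default_factory=dict)
    # demand, injured persons / period; per-scenario override wins over multiplier
    demand: list[float] = Field(default_factory=list)
    demand_by_scenario: dict[str, list[float]] = Field(default_factory=dict)
    # distances, km
    dist_coll_center: dict[str, dict[str, float]] = Field(default_factory=dict)
    dist_center_treat: dict[str, dict[str, float]] = Field(default_factory=dict)
    # costs and parameters
    unit_transport_cost: float = 5000.0
    unit_test_cost: float = 5000.0
    vehicle_capacity: float = 100.0
    alpha: float = 0.8
    beta: float = 0.8
    lam: float = 0.7
    units_per_patient: float = 1.0
    initial_inventory: dict[str, float] = Field(default_factory=dict)

    # ---- site accessors ------------------------------------------------

    def sites_of(self, kind: SiteKind) -> list[FacilitySite]:
        return [s for s in self.sites if s.kind == kind]

    @property
    def temp_sites(self) -> list[FacilitySite]:
        return self.sites_of(SiteKind.temporary_collection)

    @property
    def perm_sites(self) -> list[FacilitySite]:
        return self.sites_of(SiteKind.permanent_facility)

    @property
    def center_sites(self) -> list[FacilitySite]:
        return self.sites_of(SiteKind.blood_center)

    @property
    def field_sites(self) -> list[FacilitySite]:
        return self.sites_of(SiteKind.field_hospital)

    @property
    def treat_sites(self) -> list[FacilitySite]:
        """Treatment nodes: existing treatment centers plus candidate field hospitals."""
        return self.sites_of(SiteKind.treatment_center) + self.sites_of(
            SiteKind.field_hospital
        )

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def site(self, sid: str) -> FacilitySite:
        for s in self.sites:
            if s.id == sid:
                return s
        raise KeyError(f"unknown site id {sid!r}")

    # ---- derived quantities -------------------------------------------

    def distance(self, a: str, b: str) -> float:
        """Distance a→b from the explicit matrices, else Euclidean from coordinates."""
        row = self.dist_coll_center.get(a) or self.dist_center_treat.get(a)
        if row is not None and b in row:
            return row[b]
        sa, sb = self.site(a), self.site(b)
        if sa.x is None or sb.x is None or sa.y is None or sb.y is None:
            raise KeyError(f"no distance for arc {a!r} -> {b!r}")
        return math.hypot(sa.x - sb.x, sa.y - sb.y)

    def transfusion_demand(self, t: int, scenario: Optional[str] = None) -> float:
        """alpha * units_per_patient * injured persons in period t (units)."""
        return self.alpha * self.units_per_patient * self.persons_demand(t, scenario)

    def persons_demand(self, t: int, scenario: Optional[str] = None) -> float:
        if scenario is None:
            return self.demand[t]
        if scenario in self.demand_by_scenario:
            return self.demand_by_scenario[scenario][t]
        spec = self.scenario(scenario)
        return self.demand[t] * spec.demand_multiplier

    def scenario(self, sid: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.id == sid:
                return s
        raise KeyError(f"unknown scenario id {sid!r}")

    def init_inventory(self, z: str) -> float:
        return self.initial_inventory.get(z, 0.0)


# ---------------------------------------------------------------------------
# validation


def validate_instance(inst: NetworkInstance) -> list[str]:
    """Return diagnostics for every violated instance invariant (empty iff valid).

    Total: never raises; each diagnostic names the invariant and the
    offending element.
    """
    diags: list[str] = []
    try:
        _collect_diagnostics(inst, diags)
    except Exception as exc:  # pragma: no cover - guard for malformed objects
        diags.append(f"internal: validation aborted: {exc}")
    return diags


def _collect_diagnostics(inst: NetworkInstance, diags: list[str]) -> None:
    T = inst.n_periods
    if T == 0:
        diags.append("periods: at least one period is required")
    ids = [s.id for s in inst.sites]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        diags.append(f"sites: duplicate ids {dupes}")

    for name, val, lo_open in (
        ("alpha", inst.alpha, True),
        ("beta", inst.beta, True),
        ("lam", inst.lam, True),
    ):
        if not (0 < val <= 1):
            diags.append(f"params: {name}={val} outside (0, 1]")
    if inst.vehicle_capacity <= 0:
        diags.append("params: vehicle_capacity must be > 0")
    for name, val in (
        ("unit_transport_cost", inst.unit_transport_cost),
        ("unit_test_cost", inst.unit_test_cost),
        ("units_per_patient", inst.units_per_patient),
    ):
        if val < 0:
            diags.append(f"params: {name}={val} must be >= 0")

    psum = sum(s.probability for s in inst.scenarios)
    if not inst.scenarios:
        diags.append("scenarios: at least one scenario is required")
    elif abs(psum - 1.0) > PROB_TOL:
        diags.append(f"scenarios: scenario probabilities sum != 1 (sum={psum})")

    def check_caps(table: dict[str, list[float]], kind: SiteKind, label: str) -> None:
        want = {s.id for s in inst.sites_of(kind)}
        for sid in want:
            if sid not in table:
                diags.append(f"{label}: missing capacity row for site {sid}")
        for sid, row in table.items():
            if sid not in want:
                diags.append(f"{label}: capacity row for non-{kind.value} site {sid}")
                continue
            if len(row) != T:
                diags.append(f"{label}[{sid}]: expected {T} periods, got {len(row)}")
            for t, v in enumerate(row):
                if v < 0:
                    diags.append(f"{label}[{sid},{t}] = {v} is negative")

    check_caps(inst.capa_temp, SiteKind.temporary_collection, "capa_temp")
    check_caps(inst.capa_perm, SiteKind.permanent_facility, "capa_perm")
    check_caps(inst.capd_center, SiteKind.blood_center, "capd_center")

    for s in inst.treat_sites:
        if s.id not in inst.capf_treat:
            diags.append(f"capf_treat: missing capacity for treatment node {s.id}")
        elif inst.capf_treat[s.id] < 0:
            diags.append(f"capf_treat[{s.id}] = {inst.capf_treat[s.id]} is negative")

    if len(inst.demand) != T:
        diags.append(f"demand: expected {T} periods, got {len(inst.demand)}")
    for t, v in enumerate(inst.demand):
        if v < 0:
            diags.append(f"demand[{t}] = {v} is negative")
    known_scen = {s.id for s in inst.scenarios}
    for sid, row in inst.demand_by_scenario.items():
        if sid not in known_scen:
            diags.append(f"demand_by_scenario: unknown scenario {sid}")
        if len(row) != T:
            diags.append(f"demand_by_scenario[{sid}]: expected {T} periods")
        for t, v in enumerate(row):
            if v < 0:
                diags.append(f"demand_by_scenario[{sid}][{t}] = {v} is negative")

    # distance completeness: every collection site to every center, every
    # center to every treatment node (explicit matrix or coordinates)
    coll = inst.temp_sites + inst.perm_sites
    for a_list, b_list, label in (
        (coll, inst.center_sites, "dist_coll_center"),
        (inst.center_sites, inst.treat_sites, "dist_center_treat"),
    ):
        for a in a_list:
            for b in b_list:
                try:
                    d = inst.distance(a.id, b.id)
                except KeyError:
                    diags.append(
                        f"{label}: incomplete distance matrix, missing {a.id} -> {b.id}"
                    )
                    continue
                if d < 0:
                    diags.append(f"{label}[{a.id},{b.id}] = {d} is negative")

    for z, v in inst.initial_inventory.items():
        if v < 0:
            diags.append(f"initial_inventory[{z}] = {v} is negative")


# ---------------------------------------------------------------------------
# scenario restriction


def restrict_to_scenario(inst: NetworkInstance, scenario_id: str) -> NetworkInstance:
    """Collapse to a deterministic instance under one scenario.

    All of the scenario's multipliers are applied to the base data and the
    resulting instance carries a single scenario of probability 1.
    """
    spec = inst.scenario(scenario_id)  # raises KeyError for unknown ids
    out = inst.model_copy(deep=True)
    out.id = f"{inst.id}__{scenario_id}"
    m_cap = spec.capacity_multiplier
    out.capa_temp = {k: [v * m_cap for v in row] for k, row in inst.capa_temp.items()}
    out.capa_perm = {k: [v * m_cap for v in row] for k, row in inst.capa_perm.items()}
    out.capd_center = {
        k: [v * m_cap for v in row] for k, row in inst.capd_center.items()
    }
    out.capf_treat = {k: v * m_cap for k, v in inst.capf_treat.items()}
    out.demand = [inst.persons_demand(t, scenario_id) for t in range(inst.n_periods)]
    out.demand_by_scenario = {}
    # setup-cost multiplier applies to temporary collection sites only
    out.sites = [
        s.model_copy(
            update={"setup_cost": s.setup_cost * spec.setup_cost_multiplier}
        )
        if s.kind == SiteKind.temporary_collection
        else s
        for s in inst.sites
    ]
    out.scenarios = [
        ScenarioSpec(id=scenario_id, probability=1.0)
    ]
    return out


# ---------------------------------------------------------------------------
# I/O


class InstanceFormatError(ValueError):
    """Raised when an instance file is malformed; message names the field."""


def _canonical_dict(inst: NetworkInstance) -> dict:
    d = inst.model_dump(mode="json")
    return d


def save_instance(inst: NetworkInstance, path: str | Path) -> None:
    """Write the instance as canonical JSON (sorted keys, declared site order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_canonical_dict(inst), fh, sort_keys=True, indent=2)
        fh.write("\n")


def _load_matrix_csv(base: Path, ref: str) -> dict[str, dict[str, float]]:
    df = pd.read_csv(base / ref, index_col=0)
    return {
        str(r): {str(c): float(df.loc[r, c]) for c in df.columns} for r in df.index
    }


def load_instance(path: str | Path) -> NetworkInstance:
    """Load and validate an instance from JSON (with optional CSV sidecars).

    The two distance matrices and the base demand vector may be given as
    ``{"csv": "relative/path.csv"}`` instead of inline values; CSV matrices
    carry site ids as row/column headers.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InstanceFormatError(f"{path}: not valid JSON: {exc}") from exc

    for key in ("dist_coll_center", "dist_center_treat"):
        v = raw.get(key)
        if isinstance(v, dict) and set(v) == {"csv"}:
            raw[key] = _load_matrix_csv(path.parent, v["csv"])
    v = raw.get("demand")
    if isinstance(v, dict) and set(v) == {"csv"}:
        df = pd.read_csv(path.parent / v["csv"])
        raw["demand"] = [float(x) for x in df[df.columns[-1]]]

    try:
        inst = NetworkInstance.model_validate(raw)
    except Exception as exc:
        raise InstanceFormatError(f"{path}: schema violation: {exc}") from exc

    diags = validate_instance(inst)
    if diags:
        raise InstanceFormatError(f"{path}: invalid instance: " + "; ".join(diags))
    return inst
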