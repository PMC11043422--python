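# Methods

## Problem and model

The package designs a three-echelon post-disaster blood supply chain:
collection (temporary sites opened ad hoc, plus permanent hospitals and
clinics), processing (blood centers that test incoming units and hold
inventory), and treatment (existing centers and candidate field
hospitals). Decisions are binary facility opens plus continuous per-period
flows, inventory and shortage. Demand arrives as injured persons per
period and is converted to transfusion demand by `α × units_per_patient`
(α = fraction of the injured needing transfusion, default 0.8;
`units_per_patient` defaults to 1 because demand data of this kind rarely
distinguishes persons from units — both readings are supported). A uniform
testing pass rate β (default 0.8) is applied at the blood-center intake:
of every raw unit shipped in, β units become usable. A service-level
parameter λ (default 0.7) forces deliveries to cover at least λ of each
period's transfusion demand; shortage `IB_t` absorbs the remainder
exactly (`delivered + IB_t = α·Dem_t`).

Two objectives conflict: total cost (setup of newly opened candidates,
transport priced per unit·km on all three arc layers, testing priced per
raw unit entering a center) and shortage. The shortage objective is total
units by default; the per-period ratio sum is also computed and can be
optimized instead. Existing facilities are open by construction: their
binaries are fixed to 1, no setup cost is charged, and no open-linkage
rows are emitted.

One printed linkage family (delivery requires an open permanent-facility
destination) is vacuous under this index partition — treatment nodes are
either existing centers (always open) or field hospitals, whose linkage is
its own family — so the destination-open logic lives entirely in the
field-hospital family.

## Big-M tightening

Each open-linkage row gets its own M equal to the tightest bound valid in
every feasible solution: the site's collection capacity for collection
links; `min(collection capacity, center intake capacity)` for shipment
links; `min(treatment capacity, β·cumulative center intake + initial
inventory, period transfusion demand)` for delivery links. Tests confirm
the optimum is invariant to replacing all of these with 1e9.

## Multi-objective drivers

Raw cost (~1e9 Rials) and shortage (~1e3 units) are incommensurable, so
the weighted method normalizes each objective by `max(its ideal value, 1)`
before weighting; an optional hard cost bound reproduces the hybrid
"weighted with cost as a constraint" usage. The epsilon-constraint driver
minimizes shortage under a cost ceiling swept over an equally spaced grid
between the two anchor costs, with a second lexicographic pass per ceiling
(re-minimize cost at the attained shortage) so reported points are not
artifacts of solver tie-breaking; results are non-dominance filtered. The
eps ceiling carries a 1e-9-relative slack so that the left endpoint is not
cut off by floating-point rounding of the cost ideal.

## Scenario model

Scenarios multiply demand, temporary-facility setup costs and capacities;
probabilities must sum to 1. First-stage opens are shared across scenarios
(nonanticipativity by construction); recourse flows are replicated per
scenario. The default objective is expected scenario cost plus a per-unit
fine on expected shortage; a min–max mode replaces the expectation with
the worst scenario's cost-plus-fine via a standard epigraph variable. The
service level is enforced per scenario (the stricter reading). The default
fine grid spans 0 to 5·10^6 Rials per unit and includes the case-study
value 1,450,000.

## Synthetic generator

No numeric network data for the Kermanshah case is published (it exists
only in figures), so the case profile emulates its shape and everything
that is stated numerically: 8 temporary sites, 5 permanent facilities
(2 existing), 3 blood centers (1 existing, candidate setup fixed at 1e9
Rials), 5 existing treatment centers, 5 candidate field hospitals,
4 periods, 3 scenarios with probabilities 0.15/0.35/0.5 and demand
multipliers 0.8/1.0/1.3 (severity increasing), α = β = 0.8, λ = 0.7,
vehicle capacity 100 units, transport and testing at 5,000 Rials. The
unpublished magnitudes are fixed once at values realistic for an urban
disaster of this scale: base demand 3,000–6,000 injured in the first
24 h with a front-loaded decay (1.0/0.7/0.45/0.25) reflecting the
emergency framing; distances uniform in 1–30 km (urban road scale);
per-period collection capacities 200–400 (temporary) and 400–800
(permanent) units; center intake 2,000–5,000; treatment 1,500–4,000;
temporary setup 2–5 million Rials, far below the 1e9 blood-center setup so
the qualitative trade-off (centers expensive, temporary sites cheap) is
preserved; harsher scenarios carry setup-cost multipliers above 1
(excavation/shipping surcharges) and mild capacity relief (1.0/1.05/1.1).
An optional derivation `capacity = beds × donation hours` is available by
supplying those numbers; it is not used by the default profile because its
inputs are also unpublished.

The generator emulates the structure of real case data, not its values:
passing tests show the algorithms are correct on networks of this shape,
not that any specific real network behaves this way. Real road distances,
correlated demand surges and heterogeneous per-site behavior are outside
what the uniform draws represent.

`generate_tiny` draws integer-valued instances with at most 3 sites per
class, 2 periods and 2 scenarios, guaranteeing at most 4096 facility
configurations so the brute-force oracles finish in well under a second.

## Verification

The checker re-evaluates every constraint family's residual straight from
the data with no shared assembly code; linkage families are checked
logically (positive flow through a closed facility is a violation of that
flow's magnitude), making the check independent of big-M values.

The shortage oracle enumerates facility configurations and runs max-flow
on a time-expanded network (source → open collection sites per period →
center intake/outflow node pairs with the intake capacity on the internal
arc → inventory arcs between consecutive periods → treatment nodes capped
by their capacity → per-period demand sinks). β is handled by working in
raw units: every capacity downstream of testing is divided by β and
delivered units are β times the raw flow — exact because β is a single
uniform multiplier applied at one layer, so raw and post-testing flows are
in bijection with value ratio β. λ-feasibility is certified by max-flow
with sink capacities set to the λ requirements: saturation of all sinks is
equivalent (by max-flow/min-cut over sink-side cuts) to every subset of
periods being jointly coverable, and a feasible requirement vector extends
to a maximum total flow, so the λ constraint never changes the minimum
total shortage when it is satisfiable.

The cost oracle solves, per λ-feasible configuration, a min-cost flow
delivering exactly the λ requirement (delivering more only adds cost,
since all unit costs are non-negative) using a hand-rolled successive
shortest-path routine with Bellman–Ford path search on the residual graph;
it is written by hand because library min-cost-flow routines require
integer capacities while the β-rescaled quantities are rational.

## Numerical choices

MIP relative gap 1e-6 (default), single-threaded HiGHS via
`scipy.optimize.milp` for determinism. Extracted values are snapped to
integers/zero within 1e-7 to keep serialized solutions canonical;
instance and solution files are JSON with sorted keys so identical seeds
give byte-identical files. Checker tolerance is 1e-6 absolute; cost
comparisons against the oracle use 1e-6 relative. Periods with zero
demand contribute zero to the shortage ratio and must carry zero
shortage. Ties among optimal solutions are not stabilized beyond the
lexicographic pass in the front driver; tests compare objective values
only.

Problem sizes used in the test and acceptance runs — 50 tiny instances
for oracle cross-validation, 20 for the collapse identity, 4–5 point
fronts, and one case-profile instance per run — were chosen so the whole
suite certifies every property in seconds while the case-scale solve
exercises the full 26-site, 3-scenario model.

## Known limitations

No blood-group or product compartments, no perishability beyond a single
inventory pool, no waiting-time costs (no defensible formula or data
exists for them), no routing — transport is arc-wise with optional
integral trip counts (ceil(flow/vehicle capacity), also available inside
the MILP via integer trip variables). The min–max mode covers only the
discrete scenario set; there are no uncertainty-set robust counterparts,
chance constraints or EVPI/VSS analytics. The oracles are limited to tiny
instances by design; at case scale correctness rests on the independent
checker plus the MILP's optimality certificate.
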