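# Methods

## Problem and scope

Two computations share one domain model (point layers in projected planar
feet):

1. **Compliance audit.** Given observed outlets, protected facilities and
   census blocks, find every violation of the two dispersion rules —
   outlet–outlet separation Γ_o (default 200 ft) and outlet–facility buffer
   Γ_f (default 300 ft) — and summarize the pattern (variance set,
   nearest-neighbor means, densities, per-block counts, quota allowance).
2. **Allocation model.** Estimate the long-run outlet distribution under
   privatization as the maximum-benefit set of commercial parcels that is
   pairwise ≥ Γ_o apart and ≥ Γ_f from every protected facility — an
   anti-covering location problem, i.e. maximum-weight independent set
   (MWIS) on the geometric conflict graph.

Out of scope by design: street-network distances, point-pattern inference
(Ripley's K etc.), map rendering (a per-block count CSV is exported for
external choropleths), CRS handling, and any temporal turnover dynamics —
the model is a one-shot, static optimization.

## Conventions that matter

- **Strict inequality.** "Within X feet" means d < X everywhere, so a pair
  at exactly 200 ft (or a school at exactly 300 ft) is compliant —
  consistent with "at least 300 feet" being satisfied at 300. The audit and
  the model use the same convention, so a verified solution and a clean
  audit agree at the boundary.
- **Centroid-to-centroid distances.** Parcels, outlets and facilities are
  points. Statutes often measure property lines; centroid measurement is a
  documented approximation, not a claim about any agency's GIS procedure.
- **Ambiguous counts are reported both ways.** Facility-proximity
  "instances" are emitted as both the (outlet, facility) pair count and the
  distinct-outlet count; citywide density is emitted both as total outlets
  over total land area and as the mean of per-block densities. The variance
  set always uses distinct outlets (the only way "X of N outlets require a
  variance" is well defined).
- **Determinism.** No randomized tie-breaking anywhere; ties break by
  ascending id. Identical config + seed reproduce byte-identical layer and
  report files (run-log timings aside).

## Audit engine

Pair searches use a k-d tree (`scipy.spatial.cKDTree`) but are
contractually equal to the exhaustive O(n²) scan — the tree reports d ≤ r,
and pairs at exactly r are filtered to restore strict inequality. The
generator's ground-truth ledger (an independent chunked O(n²) scan) is the
oracle for this equality in the tests. Per-block counts assign a point on
a shared boundary to the lowest block id (shapely `covered_by` plus a
deterministic tie-break). Zero total roadway yields an absent roadway
density, never an infinity. The quota allowance is floor(population /
3,000) retail and floor(population / 30,000) wholesale.

## Allocation model

**Eligibility** is unary: commercial land use and nearest protected
facility ≥ Γ_f (kinds configurable; all five by default, including parks,
since the protected list in practice includes parks and playgrounds even
where a statute sentence names only playgrounds). **Conflict edges** join
eligible parcels at d < Γ_o. Benefits default to α_k = 1 (`uniform`): no
benefit field exists in the policy statement and the quantity of interest
is a count; a per-parcel `field` scheme is supported for extensions.

**Exact solver.** Per connected component, bitmask branch-and-bound:
branch on the maximum-degree unresolved node (include-and-delete-neighbors
vs. exclude, include explored first), prune with a greedy clique-cover
upper bound (cliques absorb vertices in ascending-id order; bound is the
sum of per-clique maximum weights), warm-started by a benefit/(degree+1)
greedy incumbent. Completing the search yields `optimal`; hitting the time
limit returns the best incumbent as `feasible_time_limit`. Geometric
conflict graphs at realistic parcel densities decompose into small
components, which is why the exact path stays cheap far beyond toy sizes.

**Greedy solver.** Repeatedly select the remaining node maximizing
benefit/(degree+1) (ties ascending id), delete it and its neighbors; then
a 2-improvement pass replaces one selected node by two mutually
non-adjacent excluded nodes whose only selected neighbor it was, whenever
that raises the objective (bounded passes), and maximality is restored.
Output is always a maximal independent set, hence ordinance-feasible.

**Dispatch.** `auto` uses exact up to 2,000 conflict-graph nodes, greedy
beyond — a desk-scale crossover, configurable.

**Grandfathering.** Default off: the headline scenario is the long-run one
in which existing licenses are not protected. When parcel ids are
grandfathered they are forced into the solution and their conflict
neighbors removed; two grandfathered parcels closer than Γ_o are *both*
kept and logged as warnings, mirroring real-world variances.

**Verification** re-runs the full audit engine on the selected parcels
treated as outlets. For any solver-produced, non-grandfathered solution the
ledger must be empty; the test suite asserts this across both solvers on
randomized instances.

## Synthetic-city generator

What it emulates: layer counts typical of a large ABC-state city (defaults:
1,964 outlets in the observed license-type mix 5.9/5.6/6.5/75% renormalized;
376 schools, 1,798 churches, 39 hospitals, 122 parks+playgrounds split
evenly; 50,000 parcels standing in for 569,928 — a desk-scale choice),
a ~134 sq mi extent matching Philadelphia's land area, the 2010 census
population 1,526,006 (so the retail quota allowance computes to 508), a
central entertainment district holding 12% of outlets on 0.6% of the land,
and a grid of census blocks with multinomial population and gamma-distributed
roadway feet (shape 4, configured mean 32,000 ft — total roadway then puts
the observed roadway density near the reported scale; any positive skewed
choice would do).

Mechanics: compliant outlets come from sequential rejection sampling with a
hard-core radius Γ_o and a facility-buffer check (a Matérn-II-style
construction); an unplaceable request raises a capacity error reporting how
many points fit. Violators are planted at uniform angle and radius in
[0.25Γ_o, 0.95Γ_o] from hosts drawn *without replacement* from the
compliant outlets, so each violator contributes a distinct violating pair;
the default 472 violators therefore implicate ≈ 944 distinct outlets —
about 48% of 1,964 — reproducing the observed variance share as a property
of the stated world rather than a fitted number. Commercial parcels are
oversampled 3× inside the district. One RNG stream per layer, all spawned
from the master seed, so changing one layer's count leaves the others
untouched.

What it does **not** emulate — and hence what a green test does not
establish: real street networks and parcel geometry, demographic
covariates, the spatial autocorrelation of actual commercial zoning, or
facility layers that cluster with outlets. Absolute synthetic statistics
(nearest-neighbor means, densities, the modeled outlet count) are
data-dependent analogues, not predictions; only directions and identities
are asserted.

## Numerical choices and degenerate inputs

- Distances in float64; the strict-inequality filter recomputes the exact
  pair distance, so boundary cases at representable coordinates are exact.
- Nearest-neighbor mean requires ≥ 2 points (error below that); duplicated
  points give distance 0, not an error.
- Variance fraction is undefined (error) for zero outlets; an empty city
  audits to empty ledgers and a zero-violation report.
- JSON round-trips preserve integers exactly and floats to full repr
  precision; feature order is a pure function of ids.
- Seeds are `numpy.random.SeedSequence` children of the master seed; all
  derived seeds stay below 2³¹.

## Known limitations

- The greedy solver carries no approximation guarantee; on unit-weight
  geometric instances it usually matches the exact optimum (asserted on
  small instances), but the reported `status` is the only claim made.
- The exact solver's worst case is exponential; dense non-geometric graphs
  beyond a few hundred nodes per component may hit the time limit and
  return an incumbent.
- Block assignment assumes blocks tile the study area; outlets outside
  every block are excluded from per-block counts (the citywide densities
  still count them).
- The candidate set under the `field` benefit scheme is only as meaningful
  as the supplied per-parcel benefits; no market or demand model is
  included.
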