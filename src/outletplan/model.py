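"""Anti-covering license-allocation model.

Under privatization, retailers are assumed to open as many outlets as the
ordinances allow.  With binary decision variables Z_k over candidate
commercial parcels k, benefits α_k, and conflict sets φ_k (candidates
within the minimum separation Γ of k), the model is

    maximize    Σ_k α_k Z_k
    subject to  Z_k + Z_j <= 1   for all k, j ∈ φ_k
                Z_k ∈ {0, 1}

i.e. a maximum-weight independent set on the geometric conflict graph.
Eligibility is a unary condition: only commercial parcels at least the
facility buffer (300 ft default) from every protected facility are
candidates; the pairwise rule only ever involves Γ (200 ft default).

Two solvers are provided: an exact branch-and-bound (bitmask state,
greedy clique-cover upper bounds, per-connected-component) and a scalable
greedy heuristic with a 2-improvement local search.  Both are fully
deterministic; all ties break by ascending parcel id.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .audit import AuditParams, AuditReport, run_audit
from .city import City, FacilityKind, LandUse, LicenseType, Outlet, coords
from .errors import ValidationError


class BenefitScheme(str, Enum):
    UNIFORM = "uniform"  # α_k = 1: the objective is an outlet count
    FIELD = "field"      # α_k = Parcel.benefit


class SolverKind(str, Enum):
    EXACT = "exact"
    GREEDY = "greedy"
    AUTO = "auto"


class SolutionStatus(str, Enum):
    OPTIMAL = "optimal"
    FEASIBLE_HEURISTIC = "feasible_heuristic"
    FEASIBLE_TIME_LIMIT = "feasible_time_limit"


#: auto-solver crossover: exact up to this many conflict-graph nodes
AUTO_EXACT_MAX_NODES = 2_000


@dataclass
class ModelConfig:
    min_outlet_separation_ft: float = 200.0
    facility_buffer_ft: float = 300.0
    facility_kinds: frozenset[FacilityKind] = frozenset(FacilityKind)
    benefit_scheme: BenefitScheme = BenefitScheme.UNIFORM
    grandfathered_parcel_ids: frozenset[str] = frozenset()
    solver: SolverKind = SolverKind.AUTO
    time_limit_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_outlet_separation_ft <= 0 or self.facility_buffer_ft <= 0:
            raise ValidationError("separation and buffer distances must be positive")
        if self.time_limit_s <= 0:
            raise ValidationError("time_limit_s must be positive")
        self.facility_kinds = frozenset(FacilityKind(k) for k in self.facility_kinds)
        self.benefit_scheme = BenefitScheme(self.benefit_scheme)
        self.solver = SolverKind(self.solver)
        self.grandfathered_parcel_ids = frozenset(self.grandfathered_parcel_ids)


@dataclass
class ConflictGraph:
    """Nodes are candidate parcel ids; edges join pairs closer than Γ."""

    nodes: list[str]
    adjacency: dict[str, set[str]]
    benefits: dict[str, float]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for k, nbrs in self.adjacency.items():
            if k in nbrs:
                raise ValidationError(f"conflict graph is reflexive at {k!r}")
            for j in nbrs:
                if j not in node_set:
                    raise ValidationError(f"adjacency of {k!r} references non-node {j!r}")
                if k not in self.adjacency.get(j, ()):
                    raise ValidationError(f"adjacency not symmetric at ({k!r}, {j!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


@dataclass
class Solution:
    selected: set[str]
    objective: float
    status: SolutionStatus
    solver_log: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected": sorted(self.selected),
            "objective": self.objective,
            "status": self.status.value,
            "solver_log": self.solver_log,
        }


def eligible_parcels(city: City, config: ModelConfig) -> list[str]:
    """Candidate parcel ids: commercial, and >= buffer from every protected facility.

    A parcel at exactly the buffer distance is eligible ("at least 300
    feet" is satisfied at 300).  Result is in ascending-id order.
    """
    commercial = [p for p in city.parcels if p.land_use == LandUse.COMMERCIAL]
    if not commercial:
        return []
    facs = [f for f in city.facilities if f.kind in config.facility_kinds]
    keep = commercial
    if facs:
        tree = cKDTree(coords(facs))
        d, _ = tree.query(coords(commercial))
        keep = [p for p, dist in zip(commercial, d)
                if not dist < config.facility_buffer_ft]
    return sorted((p.id for p in keep))


def build_conflict_graph(
    city: City, eligible: Sequence[str], config: ModelConfig
) -> ConflictGraph:
    """Edges between eligible parcels at strict distance < Γ; benefits per scheme."""
    by_id = city.parcel_by_id()
    missing = [e for e in eligible if e not in by_id]
    if missing:
        raise ValidationError(f"eligible ids not in city parcels: {missing[:5]}")
    nodes = sorted(eligible)
    parcels = [by_id[i] for i in nodes]
    adjacency: dict[str, set[str]] = {i: set() for i in nodes}
    if len(nodes) >= 2:
        pts = coords(parcels)
        tree = cKDTree(pts)
        gamma = config.min_outlet_separation_ft
        for i, j in tree.query_pairs(gamma):
            if math.hypot(*(pts[i] - pts[j])) < gamma:
                adjacency[nodes[i]].add(nodes[j])
                adjacency[nodes[j]].add(nodes[i])
    if config.benefit_scheme == BenefitScheme.UNIFORM:
        benefits = {i: 1.0 for i in nodes}
    else:
        benefits = {i: by_id[i].benefit for i in nodes}
    return ConflictGraph(nodes=nodes, adjacency=adjacency, benefits=benefits)


# ---------------------------------------------------------------------------
# exact solver: per-component bitmask branch and bound


def _components(nodes: Sequence[str], adjacency: dict[str, set[str]]) -> list[list[str]]:
    seen: set[str] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in sorted(adjacency[v]):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


def _clique_cover_bound(mask: int, adj: list[int], weights: list[float],
                        order: list[int]) -> float:
    """Upper bound on remaining weight: greedy clique partition, max weight each."""
    cliques: list[tuple[int, float]] = []  # (member mask, max weight)
    m = mask
    for v in order:
        bit = 1 << v
        if not m & bit:
            continue
        placed = False
        for idx, (cm, cw) in enumerate(cliques):
            if cm & ~adj[v] == 0:  # v adjacent to every clique member
                cliques[idx] = (cm | bit, max(cw, weights[v]))
                placed = True
                break
        if not placed:
            cliques.append((bit, weights[v]))
    return sum(cw for _, cw in cliques)


def _solve_component_exact(
    comp: list[str], adjacency: dict[str, set[str]], benefits: dict[str, float],
    deadline: float,
) -> tuple[set[str], float, int, bool]:
    """Max-weight independent set for one connected component.

    Returns (witness, weight, branch count, completed).  Branching picks the
    maximum-degree unresolved node (ties by ascending id); the upper bound is
    a greedy clique-cover.  Deterministic: the first incumbent of the best
    weight encountered in DFS order is kept.
    """
    n = len(comp)
    index = {v: i for i, v in enumerate(comp)}
    weights = [benefits[v] for v in comp]
    adj = [0] * n
    for v in comp:
        for u in adjacency[v]:
            adj[index[v]] |= 1 << index[u]
    order = list(range(n))  # ascending id (comp is sorted)

    # greedy incumbent: max weight/(degree+1), ties by index
    def _greedy(mask: int) -> tuple[int, float]:
        sel, w = 0, 0.0
        m = mask
        while m:
            best_v, best_score = -1, -1.0
            for v in order:
                if m & (1 << v):
                    deg = bin(adj[v] & m).count("1")
                    score = weights[v] / (deg + 1)
                    if score > best_score:
                        best_v, best_score = v, score
            sel |= 1 << best_v
            w += weights[best_v]
            m &= ~(adj[best_v] | (1 << best_v))
        return sel, w

    full = (1 << n) - 1
    best_sel, best_w = _greedy(full)
    branches = 0
    completed = True
    # DFS stack of (mask, current selection mask, current weight)
    stack: list[tuple[int, int, float]] = [(full, 0, 0.0)]
    while stack:
        if branches % 256 == 0 and time.monotonic() > deadline:
            completed = False
            break
        mask, cur_sel, cur_w = stack.pop()
        if mask == 0:
            if cur_w > best_w:
                best_w, best_sel = cur_w, cur_sel
            continue
        if cur_w + _clique_cover_bound(mask, adj, weights, order) <= best_w:
            # prune; equal bound cannot beat the incumbent
            if cur_w > best_w:
                best_w, best_sel = cur_w, cur_sel
            continue
        branches += 1
        # branch vertex: max degree within mask, ties by ascending index
        best_v, best_deg = -1, -1
        m = mask
        for v in order:
            if m & (1 << v):
                deg = bin(adj[v] & mask).count("1")
                if deg > best_deg:
                    best_v, best_deg = v, deg
        bit = 1 << best_v
        # push exclude first so the include branch is explored first (LIFO)
        stack.append((mask & ~bit, cur_sel, cur_w))
        stack.append((mask & ~(adj[best_v] | bit), cur_sel | bit, cur_w + weights[best_v]))
    witness = {comp[v] for v in range(n) if best_sel & (1 << v)}
    return witness, best_w, branches, completed


def solve_exact(graph: ConflictGraph, time_limit_s: float = 300.0) -> Solution:
    """Provably maximum-weight independent set (status ``optimal``) unless the
    time limit expires, in which case the best incumbent is returned with
    status ``feasible_time_limit``."""
    t0 = time.monotonic()
    deadline = t0 + time_limit_s
    selected: set[str] = set()
    total = 0.0
    branches = 0
    completed = True
    for comp in _components(graph.nodes, graph.adjacency):
        wit, w, b, done = _solve_component_exact(
            comp, graph.adjacency, graph.benefits, deadline)
        selected |= wit
        total += w
        branches += b
        completed &= done
    status = SolutionStatus.OPTIMAL if completed else SolutionStatus.FEASIBLE_TIME_LIMIT
    return Solution(
        selected=selected, objective=total, status=status,
        solver_log={"solver": "exact", "branches": branches,
                    "elapsed_s": time.monotonic() - t0,
                    "n_nodes": graph.n_nodes, "n_edges": graph.n_edges},
    )


# ---------------------------------------------------------------------------
# greedy heuristic with 2-improvement local search


def _greedy_select(graph: ConflictGraph) -> set[str]:
    # classic benefit/(degree+1) greedy; deterministic, ties by ascending id
    remaining = set(graph.nodes)
    degree = {v: len(graph.adjacency[v]) for v in graph.nodes}
    selected: set[str] = set()
    while remaining:
        best = min(
            remaining,
            key=lambda v: (-graph.benefits[v] / (degree[v] + 1), v),
        )
        selected.add(best)
        dead = {best} | (graph.adjacency[best] & remaining)
        remaining -= dead
        for d in dead:
            for u in graph.adjacency[d]:
                if u in remaining:
                    degree[u] -= 1
    return selected


def _two_improve(graph: ConflictGraph, selected: set[str], max_passes: int = 10) -> set[str]:
    """Replace one selected node by two addable excluded nodes when profitable."""
    adj, w = graph.adjacency, graph.benefits
    for _ in range(max_passes):
        # excluded node -> its selected neighbors
        sel_nbrs = {v: adj[v] & selected for v in graph.nodes if v not in selected}
        # selected node s -> excluded nodes whose only selected neighbor is s
        cands: dict[str, list[str]] = {}
        for v, sn in sel_nbrs.items():
            if len(sn) == 1:
                cands.setdefault(next(iter(sn)), []).append(v)
        improved = False
        for s in sorted(selected):
            cs = sorted(cands.get(s, []))
            done = False
            for ai, a in enumerate(cs):
                for b in cs[ai + 1:]:
                    if b not in adj[a] and w[a] + w[b] > w[s]:
                        selected.remove(s)
                        selected.update((a, b))
                        improved = done = True
                        break
                if done:
                    break
            if done:
                break
        if not improved:
            break
    # restore maximality (swaps can free neighbors of other excluded nodes)
    for v in graph.nodes:
        if v not in selected and not (graph.adjacency[v] & selected):
            selected.add(v)
    return selected


def solve_greedy(graph: ConflictGraph) -> Solution:
    """Deterministic greedy heuristic; always returns a maximal independent set."""
    t0 = time.monotonic()
    selected = _greedy_select(graph)
    selected = _two_improve(graph, selected)
    return Solution(
        selected=selected,
        objective=sum(graph.benefits[v] for v in selected),
        status=SolutionStatus.FEASIBLE_HEURISTIC,
        solver_log={"solver": "greedy", "elapsed_s": time.monotonic() - t0,
                    "n_nodes": graph.n_nodes, "n_edges": graph.n_edges},
    )


# ---------------------------------------------------------------------------
# end-to-end solve and verification


def solve(city: City, config: ModelConfig | None = None) -> Solution:
    """Eligibility filter -> grandfathering -> conflict graph -> solver.

    Grandfathered parcels are forced into the solution (mirroring licenses
    that persist despite current ordinances); their conflict neighbors are
    removed from the candidate set.  Two grandfathered parcels closer than
    Γ are both retained — the real-world variance — and flagged in the
    solver log.
    """
    config = config or ModelConfig()
    by_id = city.parcel_by_id()
    warnings: list[str] = []

    gf = sorted(config.grandfathered_parcel_ids)
    for g in gf:
        if g not in by_id:
            raise ValidationError(f"grandfathered parcel {g!r} not in city")
        if by_id[g].land_use != LandUse.COMMERCIAL:
            raise ValidationError(f"grandfathered parcel {g!r} is not commercial")
    gamma = config.min_outlet_separation_ft
    for i, a in enumerate(gf):
        for b in gf[i + 1:]:
            d = math.hypot(by_id[a].x - by_id[b].x, by_id[a].y - by_id[b].y)
            if d < gamma:
                warnings.append(
                    f"grandfathered parcels {a!r} and {b!r} conflict ({d:.1f} ft)")

    eligible = eligible_parcels(city, config)
    gf_set = set(gf)
    candidates = [e for e in eligible if e not in gf_set]
    if gf:
        gf_pts = coords([by_id[g] for g in gf])
        tree = cKDTree(gf_pts)
        cand_parcels = [by_id[c] for c in candidates]
        if cand_parcels:
            d, _ = tree.query(coords(cand_parcels))
            candidates = [c for c, dist in zip(candidates, d) if not dist < gamma]

    graph = build_conflict_graph(city, candidates, config)
    kind = config.solver
    if kind == SolverKind.AUTO:
        kind = SolverKind.EXACT if graph.n_nodes <= AUTO_EXACT_MAX_NODES else SolverKind.GREEDY
    if kind == SolverKind.EXACT:
        sol = solve_exact(graph, config.time_limit_s)
    else:
        sol = solve_greedy(graph)

    if config.benefit_scheme == BenefitScheme.UNIFORM:
        gf_benefit = float(len(gf))
    else:
        gf_benefit = sum(by_id[g].benefit for g in gf)
    sol.selected |= gf_set
    sol.objective += gf_benefit
    sol.solver_log["n_eligible"] = len(eligible)
    sol.solver_log["n_grandfathered"] = len(gf)
    sol.solver_log["warnings"] = warnings
    return sol


def solution_as_outlets(city: City, solution: Solution) -> list[Outlet]:
    """Selected parcels as synthetic outlet points, for auditing/density."""
    by_id = city.parcel_by_id()
    return [
        Outlet(id=pid, x=by_id[pid].x, y=by_id[pid].y,
               license_type=LicenseType.RESTAURANT_BAR, parcel_id=pid)
        for pid in sorted(solution.selected)
    ]


def verify_solution(city: City, solution: Solution, config: ModelConfig | None = None) -> AuditReport:
    """Audit the modeled allocation as if its parcels were operating outlets.

    For any solver-produced solution with no grandfathered parcels the
    report must show zero violations of either rule — the model's defining
    property is that the future pattern never impinges on the 200-ft or
    300-ft restrictions.
    """
    config = config or ModelConfig()
    modeled = City(
        parcels=city.parcels,
        outlets=solution_as_outlets(city, solution),
        facilities=city.facilities,
        blocks=city.blocks,
    )
    params = AuditParams(
        gamma_outlet_ft=config.min_outlet_separation_ft,
        gamma_facility_ft=config.facility_buffer_ft,
        facility_kinds=config.facility_kinds,
    )
    return run_audit(modeled, params)
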